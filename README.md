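# apamaps

Analysis of 3'UTR isoform regulation from targeted 3'-end sequencing and
CLIP binding data: polyadenylation-site (PAS) cluster calling, alternative
polyadenylation (APA) change detection, positional RNA maps of
RNA-binding-protein (RBP) occupancy around regulated PAS, motif/GC/spacing
feature maps, and DMS-based accessibility statistics — together with a
synthetic-data generator with planted ground truth so the complete pipeline
runs and is tested without any external downloads.

## Who this is for

Groups quantifying tandem APA in terminal exons — e.g. from QuantSeq-style
libraries whose read 3' ends mark cleavage positions — who want to connect
condition-dependent PAS usage shifts to the binding geometry of a candidate
regulator (CLIP peaks), the cleavage/polyadenylation cis-elements
(AAUAAA/AUUAAA hexamer, UGUA enhancer), and RNA structure (DMS
reactivity).

## The method

**Cluster calling.** Per-position 3'-end counts are pooled across all
samples; clusters are maximal runs of positions with more than 10 reads,
clusters with fewer than 20 pooled reads are dropped, and each cluster's
PAS is its highest-coverage position (3'-most on ties, transcript
orientation). Internal-priming artifacts are flagged when more than 6
consecutive genomic adenosines follow the PAS or more than 7 of the 10 nt
after the cluster are A; clusters must further contain a PAS hexamer and
match a reference PAS catalogue. Relative usage of cluster *c* in sample
*s* within terminal exon *e* is
`u(c,s) = reads(c,s) / Σ_{c'∈e} reads(c',s)`.

**Change calling.** A cluster changes on knockdown (KD) when the usage
delta (KD − control) is ≥ 10% in at least 2 of 3 replicate pairs in the
same direction with no pair in the opposite direction; confidently
non-changing exons have ≥ 10 reads in every sample and no PAS moving more
than 5% in any pair. DaPars-style tables are classified by
`dPDUI = PDUI(control) − PDUI(KD)`: |dPDUI| ≥ 0.20 with adjusted p < 0.05
is regulated (positive = the RBP lengthens the 3'UTR), |dPDUI| < 0.05 with
p > 0.05 is non-changing.

**Positional statistics.** RNA maps report the per-offset fraction of
events covered by a peak around the proximal/distal PAS, with 25th/75th
percentile bands from 100 event bootstraps and per-position two-tailed
Fisher exact tests (computed with exact integer arithmetic). Motif maps
use sliding windows (10 nt for UGUA-type 4-mers, 20 nt for hexamer
6-mers), 5-nt running-mean smoothing, and two-tailed hypergeometric tests;
UGUA→hexamer spacing is the distance from the end of the nearest upstream
UGUA to the start of the hexamer nearest the PAS. DMS accessibility scores
each motif occurrence within 100 nt upstream of a PAS by the maximum
mutation rate over its adenosines with ≥ 100× coverage and compares
distributions with two-tailed Kolmogorov–Smirnov tests.

## Worked example

```sh
apamaps run-all --seed 1 --outdir run1
```

simulates the default cohort (200 terminal exons, 2 PAS each; 25
RBP-lengthened and 25 RBP-shortened exons with a 0.30 usage shift;
triplicate knockdown vs control in nuclear and cytoplasmic fractions at
~300 reads/exon) and runs every stage. `run1/report.json` contains, for
seed 1:

```
"funnel": {"called": 437, "min_total": 437, "internal_priming": 400,
           "hexamer": 400, "reference": 400, "terminal_exon": 400}
"truth_recovery": {"sensitivity": 1.0, "false_positive_rate": 0.0, ...}
"rna_map": {"dPAS": {"peak_offset": -58, "min_p": 1.9e-27, ...}, ...}
"motif_map": {"spacing_regulated_median": 120.0,
              "spacing_nonchanging_median": 50.0, ...}
"dms": {"hexamer": {"ks_D": 1.0, "ks_p": 0.0, ...}, ...}
"apa": {"compartments": {"shared": 50, "cytoplasm_specific": 0, ...}, ...}
```

Reading: 437 clusters were called, the 37 planted internal-priming decoys
were removed by the A-run filters, and all 400 true-PAS clusters survived.
All 50 regulated exons were recovered with no false calls, and every
change replicated across nuclear and cytoplasmic fractions (shared = 50),
as planted. Regulator peak enrichment peaks 58 nt upstream of the distal
PAS (planted at −50 nt, sd 15), regulated sites show the planted extended
120-nt UGUA→hexamer spacing versus 50 nt at non-changing sites, and
hexamers at regulated distal PAS are significantly less DMS-accessible
(more structured) than controls.

Each stage is also exposed on its own (`apamaps simulate`, `call-pas`,
`call-apa`, `binding-atlas`, `rna-map`, `motif-map`, `dms`) over a shared
`--outdir`; thresholds live in a YAML config (`--config`), all defaulting
to the values above.

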