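# Methods

This note documents the models, conventions, numerical choices, and known
limitations of `apamaps`. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`; nothing is asserted from
memory.

## Coordinates and sequence conventions

All intervals are 0-based half-open (BED convention); strands are `+`/`-`.
"Upstream" and "downstream" are always transcript-orientation terms: on the
minus strand, downstream means decreasing genomic coordinate and fetched
sequences are reverse complemented. U is normalized to T on input, so
motifs quoted in the RNA alphabet (UGUA, AAUAAA) are matched as DNA
(TGTA, AATAAA). Machine outputs are BED-convention; only human-readable
logs may print 1-based positions.

## PAS cluster calling

Per-position 3'-end read counts (not full-read depth — the read 3' end
marks the cleavage position in 3'-end-targeted libraries) are summed over
all samples to give one pooled track. Clusters are maximal runs of
positions with pooled count strictly greater than 10; clusters with pooled
total below 20 are dropped (or retained with a `fail_low_total` flag for
funnel reporting). The PAS is the argmax position; ties go to the 3'-most
position in transcript orientation.

Filters accumulate flags in the order low-total → internal priming →
hexamer → reference, so any subset can be reported as a funnel:

- `fail_consecutive_A`: the transcript-orientation genomic sequence
  starting immediately after the PAS begins with more than 6 consecutive
  A. "Immediately after" is position PAS+1 in transcript orientation.
- `fail_A_rich_window`: the 10 nt immediately downstream of the cluster's
  3' boundary contain more than 7 A. The two filters deliberately anchor
  differently (PAS vs cluster edge).
- `fail_no_hexamer`: neither AATAAA nor ATTAAA occurs in the sense-strand
  cluster sequence. The search interval is the strict cluster by default.
  Because the hexamer canonically ends 10–20 nt upstream of the cleavage
  position, clusters narrower than ~25 nt cannot contain it; the pipeline
  therefore exposes `hexamer_flank_upstream` (default 30 nt in the run
  configuration) to extend the search window on the 5' side to cover the
  canonical geometry. Wide clusters (the common case when many samples are
  pooled) are unaffected; the strict-interval behaviour remains the
  library default and is what the brute-force filter tests check.
- `fail_not_in_reference`: no same-strand reference site falls within
  `[start − slack, end + slack)`; slack defaults to 0 (the site must fall
  inside the cluster).

Clusters are assigned to the same-strand terminal exon containing their
PAS; when overlapping exons both contain it, the exon whose annotated 3'
end is nearest downstream wins (the cluster most plausibly terminates that
unit). Relative usage divides each cluster's per-sample count by the exon
total for that sample; exon-samples with zero total give missing values,
never zeros.

## APA change calling

Usage deltas are knockdown minus control per matched replicate pair
(replicates are paired by index). A cluster is called increased
(decreased) when at least 2 of 3 deltas are ≥ +0.10 (≤ −0.10) and no
delta lies on the opposite side of ±`opposite_tolerance`. The tolerance
defaults to 0 — any opposite-sign delta disqualifies — which is the
literal reading of "no comparison in the opposite direction"; it is
configurable because that literal rule is noise-sensitive. Confident
non-changing exons require ≥ 10 reads in every sample and no cluster
moving more than 5% in any pair.

Exon-level direction is decided by the 3'-most called cluster: distal
usage decreasing on knockdown means the protein normally promotes the
distal site (lengthens the 3'UTR), and conversely. Compartment comparison
labels an exon shared when it changes in the same direction in nuclear and
cytoplasmic fractions, and compartment-specific only when it is
confidently non-changing in the other compartment — merely unobserved is
not evidence of absence. Set overlaps are summarized by a two-tailed
Fisher exact test over the jointly quantified universe, the Jaccard
index, and the same-direction fraction of the intersection.

dPDUI classification uses the control-minus-knockdown convention:
`dPDUI = PDUI(control) − PDUI(KD)`, so positive values mean knockdown
shifts usage toward the proximal PAS, i.e. the protein normally lengthens
the 3'UTR. The subtraction order is a convention choice; this one makes
the "lengthened" label agree with the sign of the threshold rule
(≥ +0.20, p < 0.05). Between-threshold rows (e.g. |dPDUI| = 0.10 at
p = 0.01) are deliberately unclassified rather than forced into a class.

## Positional maps and exact tests

RNA maps are binary event × offset matrices (1 when ≥ 1 peak of the RBP
covers that transcript-orientation offset from the anchor), summarized as
per-offset fractions. Confidence bands are the 25th/75th percentiles of
100 bootstrap resamples of events (rows) with replacement, seeded for
determinism; identical events collapse the band to zero width. The window
is ±300 nt by default (wide enough to contain the planted −50 nt
enrichment and its tails; configurable).

Per-offset significance uses a two-tailed Fisher exact test on the
(bound, unbound) × (regulated, non-changing) table. The two-sided p is the
sum of hypergeometric outcomes whose point probability is ≤ the observed
one, computed with exact integer arithmetic (`math.comb`) so boundary ties
need no floating-point tolerance; the test suite verifies agreement with
full enumeration over every 2×2 table with margins ≤ 30 to better than
1e−9 relative, and with `scipy.stats.fisher_exact` on random tables. No
multiple-testing correction is applied per position by default (the maps
present raw p, as heat-map rows of signed −log10 p).

Motif maps count, per offset, the sequences with ≥ 1 match starting in a
sliding window: 10 nt for 4-mers, 20 nt for 6-mers. A window "at offset
x" spans [x − w/2, x + w/2); even windows are biased one nucleotide left,
a documented convention. Frequencies are smoothed with a 5-nt running
mean (10 nt for G/C content), edges shrinking rather than padding.
Significance per offset is the same exact two-tailed test (its
hypergeometric reading). G/C content excludes ambiguous bases from both
numerator and denominator; A/U content is its complement on the
unambiguous alphabet.

UGUA→hexamer spacing: per reference PAS with proximal binding (≥ 1 focal
peak within 100 nt; the binding requirement can be waived), the 150 nt
upstream are scanned; the linker is start(hexamer nearest the PAS) −
end(nearest upstream UGUA), i.e. the number of intervening nucleotides.
The measurement endpoints are a package convention (the natural "gap"
reading); sites lacking either motif contribute nothing.

DMS accessibility: positions require ≥ 100× coverage; each motif
occurrence within 100 nt upstream of a PAS is scored by the maximum
mutation rate over its covered adenosines, occurrences with no covered A
being excluded ("sufficient data" = ≥ 1 covered A). Occurrences pool
across sites by default; a per-PAS maximum mode exists behind a flag.
Group comparisons use a two-sample two-tailed Kolmogorov–Smirnov test,
exact when the smaller group has ≤ 10 observations and asymptotic
otherwise (verified against exhaustive permutation enumeration for group
sizes ≤ 6). Lower rates mean more structure.

## Gene-end extension

CLIP peak callers confined to annotated transcript ends miss binding just
downstream of the cleavage site. `extend_gene_ends` adds 500 nt on the
transcript-orientation 3' side (floored at coordinate 0); when the added
region overlaps a same-strand gene the record is flagged and its id gains
the suffix `_overlapping<GENE_ID>` so ambiguous peaks can be filtered.
Only same-strand downstream genes are flagged — the suffix exists to warn
about signal mis-assignment to the same-strand downstream unit, which
cannot happen across strands with stranded data. Extending an
already-extended set is refused (type-marked) to prevent double extension.

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes, not
raw reads. Defaults (the study conditions used throughout the tests):

- 200 terminal exons of 1100 nt on alternating strands, 2 PAS each at
  transcript offsets 400 and 1000; 12.5% of exons lengthened and 12.5%
  shortened by the regulator (50 regulated), usage shift 0.30.
- Each PAS carries a hexamer (AAUAAA/AUUAAA, random choice) ending
  10–20 nt upstream of the cleavage position and a UGUA whose end sits a
  planted linker upstream of the hexamer start: 120 nt at regulated
  distal PAS, 50 nt elsewhere (the "extended spacing" signature).
- Background sequence is uniform ACGT with A/T homopolymers broken at
  length 4, and each cleavage position is followed by a 16-nt guard in
  which A occurs at most every third base — so compliant true PAS can
  never trip the internal-priming filters. 20% of exons carry a 15-nt
  A-run decoy between the two PAS that receives Poisson(60) reads and is
  guaranteed to trip the A-rich-window filter.
- Reads: per exon and sample, Poisson(300) total, split multinomially
  over PAS; control distal usage 0.5 ± shift/2 for regulated genes (so the
  knockdown shift is exactly 0.30 in expectation), uniform 0.35–0.65 for
  non-changing genes. Read 3' ends are jittered uniformly within ±5 nt —
  multi-base clusters from cleavage heterogeneity without a sequencing
  error model. 12 samples: control/KD × nuclear/cytoplasmic × 3
  replicates; both fractions share usage vectors (co-transcriptional APA
  model) unless `cytoplasm_only_shift` plants a cytoplasm-restricted
  shift to exercise the compartment comparison.
- CLIP: regulator peaks (40 nt) at lengthened genes centered
  Normal(dPAS − 50 nt, 15 nt) in transcript coordinates, two replicates,
  plus uniform background peaks (Poisson 0.3/UTR/replicate) and a flat
  background RBP (Poisson 1/UTR); the high-confidence subset contains
  replicate-1 peaks with a replicate-2 center within 20 nt, emulating a
  reproducibility filter.
- DMS: A/C positions within 100 nt upstream of each distal PAS get
  Poisson(200) coverage and Beta-distributed mutation rates
  (concentration 50) with mean 0.01 inside motifs of regulated genes
  ("structured") and 0.10 elsewhere ("open").
- Expression/dPDUI: lognormal TPM (median ≈ 2.7) for the 90% expressed
  transcripts; dPDUI = planted control-minus-KD distal usage +
  Normal(0, 0.02); adjusted p ∈ 10^[−8,−2.5] for regulated genes, uniform
  otherwise.

Every generator draws from an independent `numpy` stream derived from
`(seed, stream_id)`, so each output is byte-identical under a fixed seed
and insensitive to the order in which generators are called.

What the cohort does *not* emulate — and hence what passing tests do not
show about real data: sequencing error and mappability, overlapping and
nested genes, more than two-to-a-few PAS per exon with realistic usage
dispersion, biological replicate variance beyond multinomial sampling,
partial internal-priming artifacts (real A-rich stretches form a
continuum, the decoys are unambiguous), CLIP peak-width and crosslink
biases, and correlated DMS noise. Recovery rates on this cohort are upper
bounds on real-data performance.

## Problem sizes and determinism

The default cohort (200 exons, ~300 reads/exon/sample, 12 samples) was
chosen so a full `run-all` completes in a few seconds and the entire test
suite in well under a minute on a single core while leaving every
statistic deeply significant under the planted effects. The acceptance
script re-derives its numbers from scratch at the same sizes. All
randomness flows from a single user seed.

## Known limitations

- The hexamer filter's strict-interval default and the funnel flank are
  two views of one ambiguity (how much context a "cluster" carries); both
  are exposed, only one can be default.
- Replicates are paired by index; a different pairing of unordered
  replicates would change borderline calls.
- The two-tailed Fisher convention ("sum of outcomes with probability ≤
  observed") is one of several in use; values can differ from mid-p or
  doubled-one-tail conventions at small margins.
- Peak-based binding analysis ignores read-level CLIP signal; peak
  fragmentation is mitigated (footprint Jaccard) but not modeled.
- The per-position map tests are presented uncorrected; treat isolated
  significant offsets accordingly (a BH option exists on the API).
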