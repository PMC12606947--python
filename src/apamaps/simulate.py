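"""Synthetic-data generator with planted ground truth.

Emulates the statistical structure of the study inputs end to end: a
genome whose terminal exons carry tandem PAS with planted hexamer/UGUA
geometry, targeted 3'-end read counts with multinomial PAS usage and
condition shifts, A-rich internal-priming decoys, positionally enriched
CLIP peaks for a "regulator" RBP, DMS accessibility with structured
motifs, and a DaPars-style dPDUI table. Every generator is byte-
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

from .apa import LENGTHENED, NON_CHANGING, SHORTENED
from .core import (
    CoverageTrack,
    DmsTrack,
    ExpressionTable,
    GenomicInterval,
    PasReferenceSite,
    PeakRecord,
    TerminalExon,
    fetch_sequence,
    from_offset,
    reverse_complement,
)
from .motifs import HEXAMER_PATTERN, UGUA_PATTERN, MotifSpec, scan_motif

import pandas as pd

CHROM = "chrS"
REGULATOR_RBP = "RBP1"
BACKGROUND_RBP = "CTRL_RBP"
CONDITIONS = ("control", "kd")
FRACTIONS = ("nuclear", "cytoplasmic")
READ_JITTER = 5  # cleavage heterogeneity: read 3' ends within +/- 5 nt
DECOY_A_RUN = 15
GUARD_LEN = 16
_BETA_CONCENTRATION = 50.0


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the targeted 3'-end sequencing design: triplicate
    knockdown vs control in nuclear and cytoplasmic fractions, a 0.30
    distal-usage shift at regulated exons, regulator CLIP peaks centered
    50 nt upstream of the distal PAS, and structured (low DMS rate) motifs
    at regulated distal sites.
    """

    n_genes: int = 200
    pas_per_exon: int = 2
    fraction_lengthened: float = 0.125
    fraction_shortened: float = 0.125
    shift_magnitude: float = 0.30
    reads_per_exon_mean: float = 300.0
    n_replicates: int = 3
    decoy_fraction: float = 0.2
    decoy_reads_mean: float = 60.0
    decoy_sample_fraction: float = 1.0
    clip_enrichment_center: int = -50
    clip_enrichment_sd: float = 15.0
    clip_peak_width: int = 40
    clip_background_per_utr: float = 0.3
    linker_regulated: int = 120
    linker_background: int = 50
    dms_structured_rate: float = 0.01
    dms_open_rate: float = 0.10
    dms_coverage_mean: float = 200.0
    dpdui_noise_sd: float = 0.02
    unexpressed_fraction: float = 0.1
    cytoplasm_only_shift: bool = False
    exon_length: int = 1100
    gene_spacing: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_lengthened", "fraction_shortened", "decoy_fraction",
                     "decoy_sample_fraction", "dms_structured_rate", "dms_open_rate",
                     "unexpressed_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.fraction_lengthened + self.fraction_shortened > 1.0:
            raise ValueError("regulated fractions must sum to <= 1")
        if not (0.0 < self.shift_magnitude < 1.0):
            raise ValueError("shift_magnitude must lie in (0, 1)")
        if self.pas_per_exon < 2:
            raise ValueError("pas_per_exon must be >= 2")
        offs = self.pas_offsets()
        max_linker = max(self.linker_regulated, self.linker_background)
        # hexamer (6) + max gap (20) + linker + UGUA (4) + buffers must fit
        if offs[0] < max_linker + 36:
            raise ValueError("exon too short for requested cis-elements")
        if self.exon_length - offs[-1] < GUARD_LEN + 4:
            raise ValueError("exon too short downstream of the distal PAS")
        if min(np.diff(offs)) < 80:
            raise ValueError("PAS spaced too closely for decoys and guards")

    def pas_offsets(self) -> list[int]:
        """Transcript offsets of the planted cleavage positions."""
        return [
            int(round(x))
            for x in np.linspace(400, self.exon_length - 100, self.pas_per_exon)
        ]

    def sample_ids(self) -> list[str]:
        return [
            f"{cond}_{frac}_rep{r}"
            for cond in CONDITIONS
            for frac in FRACTIONS
            for r in range(1, self.n_replicates + 1)
        ]

    def pairing(self, fraction: str) -> list[tuple[str, str]]:
        """Matched (knockdown, control) sample pairs for one fraction."""
        return [
            (f"kd_{fraction}_rep{r}", f"control_{fraction}_rep{r}")
            for r in range(1, self.n_replicates + 1)
        ]


@dataclass
class SimTruth:
    """Planted ground truth for recovery tests."""

    labels: dict[str, str]
    exons: list[TerminalExon]
    pas_positions: dict[str, list[int]]
    usage_control: dict[str, np.ndarray]
    usage_kd: dict[str, np.ndarray]
    decoy_positions: dict[str, int]
    linkers: dict[str, list[int]]
    hexamer_gaps: dict[str, list[int]]
    structured: dict[str, bool]
    utrs: dict[str, GenomicInterval]
    expressed: dict[str, bool]

    @property
    def genes(self) -> list[str]:
        return [ex.gene_id for ex in self.exons]

    def exon_of(self, gene_id: str) -> TerminalExon:
        return next(ex for ex in self.exons if ex.gene_id == gene_id)

    def regulated_genes(self) -> list[str]:
        return [g for g, lab in self.labels.items() if lab != NON_CHANGING]

    def to_jsonable(self) -> dict:
        return {
            "labels": self.labels,
            "pas_positions": self.pas_positions,
            "usage_control": {g: list(map(float, u)) for g, u in self.usage_control.items()},
            "usage_kd": {g: list(map(float, u)) for g, u in self.usage_kd.items()},
            "decoy_positions": self.decoy_positions,
            "linkers": self.linkers,
            "structured": self.structured,
            "expressed": self.expressed,
        }


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _scrub_runs(seq: np.ndarray, base: bytes, max_run: int = 4) -> None:
    """Break homopolymer runs of ``base`` longer than ``max_run`` in place."""
    is_base = seq == base
    breaker = b"G" if base == b"A" else b"C"
    run = 0
    for i in range(seq.size):
        if is_base[i]:
            run += 1
            if run > max_run:
                seq[i] = breaker
                run = 0
        else:
            run = 0


def _plant(seq: np.ndarray, exon: GenomicInterval, offset: int, s: str,
           buffer: bool = True) -> None:
    """Write transcript-orientation sequence ``s`` at a transcript offset."""
    payload = ("C" + s + "C") if buffer else s
    off = offset - 1 if buffer else offset
    if exon.strand == "+":
        g0 = exon.start + off
        seq[g0 : g0 + len(payload)] = np.frombuffer(payload.encode(), dtype="S1")
    else:
        rc = reverse_complement(payload)
        g_end = exon.end - off
        seq[g_end - len(payload) : g_end] = np.frombuffer(rc.encode(), dtype="S1")


def _guard(rng: np.random.Generator, n: int = GUARD_LEN) -> str:
    """Downstream sequence compatible with the internal-priming filters.

    A is allowed only at every third position (probability 0.4), so any
    10-nt window holds at most 4 adenosines and no A run exceeds one.
    """
    other = "CGT"
    out = []
    for i in range(n):
        if i % 3 == 0 and rng.random() < 0.4:
            out.append("A")
        else:
            out.append(other[rng.integers(0, 3)])
    return "".join(out)


def simulate_genome(
    config: SimConfig,
) -> tuple[dict[str, str], list[TerminalExon], list[PasReferenceSite], SimTruth]:
    """Genome, terminal-exon annotation, reference PAS list, and truth.

    Each exon carries ``pas_per_exon`` cleavage positions, each preceded by
    a PAS hexamer ending 10-20 nt upstream and a UGUA at the planted
    linker distance; a compliant low-A guard follows each cleavage site.
    Decoy exons additionally carry a 15-nt genomic A run downstream of a
    non-PAS position. The reference list holds exactly the true PAS.
    """
    rng = _rng(config, 1)
    n = config.n_genes
    chrom_len = 1000 + n * config.gene_spacing
    seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=chrom_len)
    _scrub_runs(seq, b"A")
    _scrub_runs(seq, b"T")

    # regulation labels
    order = rng.permutation(n)
    n_len = int(round(config.fraction_lengthened * n))
    n_short = int(round(config.fraction_shortened * n))
    labels = {}
    genes = [f"G{i:04d}" for i in range(n)]
    for rank, gi in enumerate(order):
        if rank < n_len:
            labels[genes[gi]] = LENGTHENED
        elif rank < n_len + n_short:
            labels[genes[gi]] = SHORTENED
        else:
            labels[genes[gi]] = NON_CHANGING

    offsets = config.pas_offsets()
    exons: list[TerminalExon] = []
    reference: list[PasReferenceSite] = []
    pas_positions: dict[str, list[int]] = {}
    usage_control: dict[str, np.ndarray] = {}
    usage_kd: dict[str, np.ndarray] = {}
    decoys: dict[str, int] = {}
    linkers: dict[str, list[int]] = {}
    hex_gaps: dict[str, list[int]] = {}
    structured: dict[str, bool] = {}
    utrs: dict[str, GenomicInterval] = {}
    expressed: dict[str, bool] = {}

    nonchanging = [g for g in genes if labels[g] == NON_CHANGING]
    n_unexpr = int(round(config.unexpressed_fraction * n))
    unexpressed = set(
        rng.choice(nonchanging, size=min(n_unexpr, len(nonchanging)), replace=False)
    ) if nonchanging else set()

    for i, gene in enumerate(genes):
        start = 500 + i * config.gene_spacing
        strand = "+" if i % 2 == 0 else "-"
        exon_iv = GenomicInterval(CHROM, start, start + config.exon_length, strand, id=gene)
        cds_end = from_offset(exon_iv.five_prime, strand, 100)
        exons.append(TerminalExon(gene, exon_iv, cds_end))

        gene_pas = []
        gene_linkers = []
        gene_gaps = []
        label = labels[gene]
        for j, off in enumerate(offsets):
            is_distal = j == len(offsets) - 1
            linker = (
                config.linker_regulated
                if (label == LENGTHENED and is_distal)
                else config.linker_background
            )
            gap = int(rng.integers(10, 21))
            hexamer = "AATAAA" if rng.random() < 0.5 else "ATTAAA"
            hex_start = off - gap - 6
            _plant(seq, exon_iv, hex_start, hexamer)
            _plant(seq, exon_iv, hex_start - linker - 4, "TGTA")
            _plant(seq, exon_iv, off + 1, _guard(rng), buffer=False)
            gene_pas.append(from_offset(exon_iv.five_prime, strand, off))
            gene_linkers.append(linker)
            gene_gaps.append(gap)
            reference.append(PasReferenceSite(CHROM, gene_pas[-1], strand))
        pas_positions[gene] = gene_pas
        linkers[gene] = gene_linkers
        hex_gaps[gene] = gene_gaps

        if rng.random() < config.decoy_fraction:
            decoy_off = (offsets[0] + offsets[1]) // 2
            _plant(seq, exon_iv, decoy_off + 1, "A" * DECOY_A_RUN, buffer=False)
            decoys[gene] = from_offset(exon_iv.five_prime, strand, decoy_off)

        # usage vectors: middle PAS hold a fixed 10% share each
        k = config.pas_per_exon
        mid_share = 0.10 * (k - 2)
        avail = 1.0 - mid_share
        if label == LENGTHENED:
            ctrl_distal = 0.5 + config.shift_magnitude / 2
            kd_distal = 0.5 - config.shift_magnitude / 2
        elif label == SHORTENED:
            ctrl_distal = 0.5 - config.shift_magnitude / 2
            kd_distal = 0.5 + config.shift_magnitude / 2
        else:
            ctrl_distal = kd_distal = float(rng.uniform(0.35, 0.65))

        def vec(distal_frac: float) -> np.ndarray:
            u = np.full(k, 0.10)
            u[-1] = distal_frac * avail
            u[0] = (1.0 - distal_frac) * avail
            return u

        usage_control[gene] = vec(ctrl_distal)
        usage_kd[gene] = vec(kd_distal)
        structured[gene] = label == LENGTHENED

        tid = f"{gene}.t1"
        if strand == "+":
            utrs[tid] = GenomicInterval(CHROM, cds_end, exon_iv.end, strand, id=tid)
        else:
            utrs[tid] = GenomicInterval(CHROM, exon_iv.start, cds_end + 1, strand, id=tid)
        expressed[tid] = gene not in unexpressed

    genome = {CHROM: seq.tobytes().decode()}
    truth = SimTruth(
        labels, exons, pas_positions, usage_control, usage_kd, decoys,
        linkers, hex_gaps, structured, utrs, expressed,
    )
    return genome, exons, reference, truth


def _kd_usage(config: SimConfig, truth: SimTruth, gene: str, fraction: str) -> np.ndarray:
    if config.cytoplasm_only_shift and fraction == "nuclear":
        return truth.usage_control[gene]
    return truth.usage_kd[gene]


def simulate_three_prime_reads(config: SimConfig, truth: SimTruth) -> list[CoverageTrack]:
    """Per-sample 3'-end count tracks with multinomial PAS usage.

    Per exon and sample, the total is Poisson(reads_per_exon_mean), split
    multinomially over the PAS with the condition usage vector; each
    read's 3' end is jittered uniformly within +/- 5 nt. Decoy positions
    receive Poisson(decoy_reads_mean) reads in a configurable fraction of
    samples.
    """
    rng = _rng(config, 2)
    tracks = []
    genes = truth.genes
    exon_by_gene = {ex.gene_id: ex for ex in truth.exons}
    for sample in config.sample_ids():
        cond, fraction, _ = sample.split("_")
        track = CoverageTrack(sample)
        for gene in genes:
            exon = exon_by_gene[gene]
            strand = exon.interval.strand
            usage = (
                truth.usage_control[gene]
                if cond == "control"
                else _kd_usage(config, truth, gene, fraction)
            )
            total = int(rng.poisson(config.reads_per_exon_mean))
            counts = rng.multinomial(total, usage) if total else np.zeros(len(usage), int)
            for pas, c in zip(truth.pas_positions[gene], counts):
                if not c:
                    continue
                jitter = rng.integers(-READ_JITTER, READ_JITTER + 1, size=int(c))
                pos, cnt = np.unique(pas + jitter, return_counts=True)
                for p, k in zip(pos, cnt):
                    track.add(exon.interval.chrom, strand, int(p), int(k))
            if gene in truth.decoy_positions and rng.random() < config.decoy_sample_fraction:
                c = int(rng.poisson(config.decoy_reads_mean))
                if c:
                    jitter = rng.integers(-READ_JITTER, READ_JITTER + 1, size=c)
                    pos, cnt = np.unique(truth.decoy_positions[gene] + jitter,
                                         return_counts=True)
                    for p, k in zip(pos, cnt):
                        track.add(exon.interval.chrom, strand, int(p), int(k))
        tracks.append(track)
    return tracks


def simulate_clip_peaks(config: SimConfig, truth: SimTruth) -> list[PeakRecord]:
    """CLIP peaks for a regulator RBP (two replicates plus a reproducible
    high-confidence subset) and a positionally flat background RBP.

    Regulator peaks at lengthened genes center on
    Normal(dPAS + clip_enrichment_center, clip_enrichment_sd) in
    transcript coordinates; background peaks are uniform over expressed
    3'UTRs. The high-confidence subset contains replicate-1 peaks with a
    replicate-2 center within 20 nt.
    """
    rng = _rng(config, 3)
    half = config.clip_peak_width // 2
    peaks: list[PeakRecord] = []
    expressed_utrs = [
        truth.utrs[tid] for tid in sorted(truth.utrs) if truth.expressed[tid]
    ]
    reg_centers: dict[str, list[tuple[str, str, int]]] = {"rep1": [], "rep2": []}
    for rep in ("rep1", "rep2"):
        for gene in truth.genes:
            if truth.labels[gene] != LENGTHENED or not truth.expressed.get(f"{gene}.t1", False):
                continue
            exon = truth.exon_of(gene)
            strand = exon.interval.strand
            dpas = truth.pas_positions[gene][-1]
            off = config.clip_enrichment_center + rng.normal(0.0, config.clip_enrichment_sd)
            center = from_offset(dpas, strand, int(round(off)))
            iv = GenomicInterval(CHROM, max(0, center - half), center - half +
                                 config.clip_peak_width, strand)
            peaks.append(PeakRecord(iv, REGULATOR_RBP, rep, "any", 1.0))
            reg_centers[rep].append((CHROM, strand, center))
        for utr in expressed_utrs:
            for _ in range(int(rng.poisson(config.clip_background_per_utr))):
                center = int(rng.integers(utr.start, utr.end))
                iv = GenomicInterval(CHROM, max(0, center - half), center - half +
                                     config.clip_peak_width, utr.strand)
                peaks.append(PeakRecord(iv, REGULATOR_RBP, rep, "any", 0.5))
                reg_centers[rep].append((CHROM, utr.strand, center))
        for utr in expressed_utrs:
            for _ in range(int(rng.poisson(1.0))):
                center = int(rng.integers(utr.start, utr.end))
                iv = GenomicInterval(CHROM, max(0, center - half), center - half +
                                     config.clip_peak_width, utr.strand)
                peaks.append(PeakRecord(iv, BACKGROUND_RBP, rep, "any", 0.5))
    # reproducible subset
    rep2_by_key: dict[tuple[str, str], list[int]] = {}
    for chrom, strand, center in reg_centers["rep2"]:
        rep2_by_key.setdefault((chrom, strand), []).append(center)
    for peak in [p for p in peaks if p.rbp_id == REGULATOR_RBP and p.replicate == "rep1"]:
        iv = peak.interval
        center = iv.start + half
        mates = rep2_by_key.get((iv.chrom, iv.strand), [])
        if any(abs(center - m) <= 20 for m in mates):
            peaks.append(PeakRecord(iv, REGULATOR_RBP, "idr", "high", peak.score))
    return peaks


def simulate_dms(
    config: SimConfig, truth: SimTruth, genome: Mapping[str, str]
) -> DmsTrack:
    """DMS coverage and mutation rates over PAS-proximal windows.

    A/C positions within 100 nt upstream of each distal PAS receive
    Poisson coverage and Beta-distributed mutation rates whose mean is
    ``dms_structured_rate`` inside motifs of structured (regulated) genes
    and ``dms_open_rate`` elsewhere.
    """
    rng = _rng(config, 4)
    track = DmsTrack()
    hexamer = MotifSpec(HEXAMER_PATTERN)
    ugua = MotifSpec(UGUA_PATTERN)
    for gene in truth.genes:
        exon = truth.exon_of(gene)
        strand = exon.interval.strand
        dpas = truth.pas_positions[gene][-1]
        if strand == "+":
            region = GenomicInterval(CHROM, max(0, dpas - 100), dpas, strand)
        else:
            region = GenomicInterval(CHROM, dpas + 1, dpas + 101, strand)
        seq = fetch_sequence(genome, region)
        in_motif = np.zeros(len(seq), dtype=bool)
        for spec in (hexamer, ugua):
            for s in scan_motif(seq, spec):
                in_motif[s : s + len(spec.pattern)] = True
        for i, base in enumerate(seq):
            if base not in "AC":
                continue
            mean = (
                config.dms_structured_rate
                if truth.structured[gene] and in_motif[i]
                else config.dms_open_rate
            )
            cov = int(rng.poisson(config.dms_coverage_mean))
            if mean <= 0.0:
                rate = 0.0
            elif mean >= 1.0:
                rate = 1.0
            else:
                rate = float(
                    rng.beta(mean * _BETA_CONCENTRATION, (1 - mean) * _BETA_CONCENTRATION)
                )
            gpos = region.start + i if strand == "+" else region.end - 1 - i
            track.set(CHROM, strand, gpos, base, cov, min(max(rate, 0.0), 1.0))
    return track


def simulate_expression_and_dpdui(
    config: SimConfig, truth: SimTruth
) -> tuple[ExpressionTable, pd.DataFrame]:
    """Control TPM table and a DaPars-style dPDUI table.

    dPDUI is control-minus-knockdown distal usage plus Gaussian noise;
    adjusted p is small for regulated genes and uniform otherwise. Only
    expressed transcripts are quantified.
    """
    rng = _rng(config, 5)
    n_ctl = config.n_replicates * len(FRACTIONS)
    table = ExpressionTable()
    rows = []
    for gene in truth.genes:
        tid = f"{gene}.t1"
        utr = truth.utrs[tid]
        if truth.expressed[tid]:
            tpms = rng.lognormal(1.0, 0.5, size=n_ctl)
        else:
            tpms = rng.uniform(0.0, 0.8, size=n_ctl)
        table.add(tid, tpms, utr)
        if not truth.expressed[tid]:
            continue
        ctrl_d = truth.usage_control[gene][-1]
        kd_d = truth.usage_kd[gene][-1]
        noise = rng.normal(0.0, config.dpdui_noise_sd) if config.dpdui_noise_sd else 0.0
        dpdui = float(np.clip(ctrl_d - kd_d + noise, -1.0, 1.0))
        if truth.labels[gene] == NON_CHANGING:
            adj_p = float(rng.uniform())
        else:
            adj_p = float(10.0 ** rng.uniform(-8.0, -2.5))
        exon = truth.exon_of(gene)
        rows.append(
            [gene, CHROM, exon.interval.strand, truth.pas_positions[gene][0],
             truth.pas_positions[gene][-1], dpdui, adj_p]
        )
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "strand", "ppas", "dpas", "dpdui", "adjusted_p"],
    )
    return table, df
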