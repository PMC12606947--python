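"""Domain types and coordinate conventions shared by every stage.

All coordinates are 0-based half-open (BED convention). "Upstream" and
"downstream" are always in transcript orientation: on the minus strand,
downstream means decreasing genomic coordinate. Sequences are handled in
the uppercase DNA alphabet; U on input is normalized to T.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from intervaltree import IntervalTree

STRANDS = ("+", "-")

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def normalize_seq(seq: str) -> str:
    """Uppercase and convert RNA (U) to DNA (T)."""
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    return normalize_seq(seq).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open stranded interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str
    id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the transcript-orientation 5' base."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        """Genomic coordinate of the transcript-orientation 3' base."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class TerminalExon:
    """A gene's last exon; ``cds_end`` (if present) marks the 3'UTR start."""

    gene_id: str
    interval: GenomicInterval
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.cds_end is not None and not (
            self.interval.start <= self.cds_end < self.interval.end
        ):
            raise ValueError(
                f"cds_end {self.cds_end} outside exon of {self.gene_id}"
            )


@dataclass(frozen=True)
class PasReferenceSite:
    """A single reference cleavage position (PolyA_DB-style)."""

    chrom: str
    position: int
    strand: str

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("reference position must be >= 0")
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")


@dataclass(frozen=True)
class PeakRecord:
    """A CLIP peak call for one RBP/replicate.

    ``confidence`` is "any" for per-replicate peaks and "high" for the
    reproducible (IDR-style) subset.
    """

    interval: GenomicInterval
    rbp_id: str
    replicate: str
    confidence: str = "any"
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.confidence not in ("any", "high"):
            raise ValueError(f"unknown confidence {self.confidence!r}")


@dataclass
class CoverageTrack:
    """Per-position 3'-end read counts for one sample.

    ``data`` maps (chrom, strand) to a Counter of position -> reads; absent
    positions are count zero.
    """

    sample_id: str
    data: dict[tuple[str, str], Counter] = field(default_factory=dict)

    def add(self, chrom: str, strand: str, position: int, count: int = 1) -> None:
        if count < 0:
            raise ValueError("coverage counts must be non-negative")
        self.data.setdefault((chrom, strand), Counter())[position] += count

    def get(self, chrom: str, strand: str, position: int) -> int:
        return self.data.get((chrom, strand), Counter()).get(position, 0)

    def total(self) -> int:
        return sum(sum(c.values()) for c in self.data.values())


@dataclass
class DmsTrack:
    """Per-position DMS coverage and mutation rate.

    ``data`` maps (chrom, strand, position) to (base, coverage, rate) where
    ``base`` is the transcript-orientation nucleotide.
    """

    data: dict[tuple[str, str, int], tuple[str, int, float]] = field(
        default_factory=dict
    )

    def set(
        self, chrom: str, strand: str, position: int, base: str, coverage: int, rate: float
    ) -> None:
        if coverage < 0:
            raise ValueError("coverage must be >= 0")
        if not (0.0 <= rate <= 1.0):
            raise ValueError("mutation rate must lie in [0, 1]")
        self.data[(chrom, strand, position)] = (normalize_seq(base), coverage, rate)

    def get(self, chrom: str, strand: str, position: int):
        return self.data.get((chrom, strand, position))


@dataclass
class ExpressionTable:
    """Per-transcript control TPM values plus the 3'UTR interval."""

    tpm: dict[str, list[float]] = field(default_factory=dict)
    utr: dict[str, GenomicInterval] = field(default_factory=dict)

    def add(self, transcript_id: str, tpms: Iterable[float], utr: GenomicInterval) -> None:
        vals = [float(v) for v in tpms]
        if any(v < 0 for v in vals):
            raise ValueError("TPM values must be non-negative")
        self.tpm[transcript_id] = vals
        self.utr[transcript_id] = utr


# ---------------------------------------------------------------------------
# transcript-orientation arithmetic

def to_offset(anchor: int, strand: str, position: int) -> int:
    """Signed transcript-orientation offset of ``position`` from ``anchor``."""
    return position - anchor if strand == "+" else anchor - position


def from_offset(anchor: int, strand: str, offset: int) -> int:
    """Genomic position at transcript-orientation ``offset`` from ``anchor``."""
    return anchor + offset if strand == "+" else anchor - offset


def fetch_sequence(genome: Mapping[str, str], interval: GenomicInterval) -> str:
    """Transcript-orientation sequence of ``interval`` from a chrom->seq map.

    Minus-strand intervals are reverse complemented; output is uppercase DNA.
    """
    if interval.chrom not in genome:
        raise KeyError(f"unknown chromosome {interval.chrom!r}")
    seq = genome[interval.chrom]
    if interval.end > len(seq):
        raise IndexError(
            f"interval {interval.chrom}:{interval.start}-{interval.end} exceeds "
            f"chromosome length {len(seq)}"
        )
    sub = normalize_seq(seq[interval.start : interval.end])
    return sub if interval.strand == "+" else reverse_complement(sub)


def downstream_sequence(
    genome: Mapping[str, str], chrom: str, strand: str, position: int, length: int
) -> str:
    """Transcript-orientation sequence of up to ``length`` bases starting
    immediately 3' of ``position`` (exclusive). Truncated at chromosome ends."""
    if length <= 0:
        return ""
    chrom_len = len(genome[chrom])
    if strand == "+":
        start = position + 1
        end = min(chrom_len, start + length)
        if start >= end:
            return ""
        return fetch_sequence(genome, GenomicInterval(chrom, start, end, "+"))
    end = position  # half-open: bases position-1 downward
    start = max(0, end - length)
    if start >= end:
        return ""
    return fetch_sequence(genome, GenomicInterval(chrom, start, end, "-"))


class IntervalIndex:
    """Strand-aware interval index over records carrying a GenomicInterval.

    Records may be GenomicInterval instances or any object with an
    ``interval`` attribute (PeakRecord, TerminalExon, ...).
    """

    def __init__(self, records: Iterable = ()):  # noqa: D401
        self._trees: dict[str, IntervalTree] = {}
        for rec in records:
            self.add(rec)

    @staticmethod
    def _interval_of(rec) -> GenomicInterval:
        return rec if isinstance(rec, GenomicInterval) else rec.interval

    def add(self, rec) -> None:
        iv = self._interval_of(rec)
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, rec)

    def query(self, probe: GenomicInterval, same_strand: bool = True) -> list:
        """Records sharing >= 1 base with ``probe`` (strand-filtered if asked)."""
        tree = self._trees.get(probe.chrom)
        if tree is None:
            return []
        hits = []
        for node in sorted(tree.overlap(probe.start, probe.end)):
            rec = node.data
            if same_strand and self._interval_of(rec).strand != probe.strand:
                continue
            hits.append(rec)
        return hits

    def query_point(self, chrom: str, position: int, strand: str | None = None) -> list:
        probe = GenomicInterval(chrom, position, position + 1, strand or "+")
        return self.query(probe, same_strand=strand is not None)
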