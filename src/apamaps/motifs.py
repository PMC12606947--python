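"""Motif scanning, positional motif-frequency maps, GC profiles, and
UGUA-to-hexamer spacing distributions.

Motifs are given in IUPAC nucleotide code (RNA or DNA alphabet; U is
normalized to T). A sliding window of 10 nt is used for 4-mers and 20 nt
for 6-mers, with a 5-nt running mean; GC profiles use a 10-nt running
mean. A window "at offset x" spans [x - w//2, x + w - w//2): even window
lengths are biased one nucleotide left of center.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import (
    GenomicInterval,
    IntervalIndex,
    PeakRecord,
    fetch_sequence,
    from_offset,
    normalize_seq,
)
from .stats import hypergeom_two_tailed

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

HEXAMER_PATTERN = "AWTAAA"  # AAUAAA / AUUAAA
UGUA_PATTERN = "TGTA"

SEARCH_RADIUS = 150
BINDING_RADIUS = 100
SMOOTH_MOTIF = 5
SMOOTH_GC = 10


@dataclass(frozen=True)
class MotifSpec:
    """An IUPAC motif and scan orientation.

    ``reverse_complement`` scans the sense sequence for the
    reverse-complemented pattern (e.g. UGUA -> UACA on the RNA level).
    """

    pattern: str
    orientation: str = "sense"

    def __post_init__(self) -> None:
        pat = normalize_seq(self.pattern)
        if not set(pat) <= set(IUPAC):
            raise ValueError(f"non-IUPAC characters in pattern {self.pattern!r}")
        if self.orientation not in ("sense", "reverse_complement"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        object.__setattr__(self, "pattern", pat)

    @property
    def scan_pattern(self) -> str:
        if self.orientation == "reverse_complement":
            return self.pattern.translate(_IUPAC_COMPLEMENT)[::-1]
        return self.pattern

    @property
    def default_window(self) -> int:
        return 10 if len(self.pattern) == 4 else 20

    def regex(self) -> re.Pattern:
        # lookahead makes overlapping matches visible
        body = "".join(
            c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in self.scan_pattern
        )
        return re.compile(f"(?=({body}))")


def scan_motif(sequence: str, spec: MotifSpec) -> list[int]:
    """Start offsets of all (overlapping) matches after T/U normalization."""
    seq = normalize_seq(sequence)
    return [m.start() for m in spec.regex().finditer(seq)]


def running_mean(values: np.ndarray, k: int) -> np.ndarray:
    """Centered running mean of length ``k`` with shrunken edge windows.

    Even ``k`` is biased one element left of center. NaNs are excluded
    from both numerator and denominator.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if k <= 1 or n == 0:
        return v.copy()
    half_l = k // 2
    half_r = k - half_l
    mask = ~np.isnan(v)
    filled = np.where(mask, v, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(filled)])
    ccount = np.concatenate([[0], np.cumsum(mask)])
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half_l)
        hi = min(n, i + half_r)
        cnt = ccount[hi] - ccount[lo]
        out[i] = (csum[hi] - csum[lo]) / cnt if cnt else np.nan
    return out


def window_match_counts(
    sequences: Sequence[str], spec: MotifSpec, window: int | None = None
) -> np.ndarray:
    """Per-offset count of sequences with >= 1 match starting in the window.

    All sequences must share their length (they are aligned on an anchor);
    the window at offset x spans [x - w//2, x + w - w//2).
    """
    if not sequences:
        return np.zeros(0, dtype=int)
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("aligned sequences must share their length")
    w = window if window is not None else spec.default_window
    half_l = w // 2
    half_r = w - half_l
    counts = np.zeros(length, dtype=int)
    for seq in sequences:
        starts = scan_motif(seq, spec)
        if not starts:
            continue
        has = np.zeros(length, dtype=bool)
        for s in starts:
            # window at offset x contains s iff x - half_l <= s < x + half_r
            lo = max(0, s - half_r + 1)
            hi = min(length, s + half_l + 1)
            has[lo:hi] = True
        counts += has
    return counts


def window_frequency(
    sequences: Sequence[str],
    spec: MotifSpec,
    window: int | None = None,
    smooth: int = SMOOTH_MOTIF,
) -> np.ndarray:
    """Smoothed per-offset fraction of sequences with a motif in the window."""
    counts = window_match_counts(sequences, spec, window)
    if counts.size == 0 or not sequences:
        return counts.astype(float)
    freq = counts / len(sequences)
    return running_mean(freq, smooth)


def positional_hypergeom(
    counts_positive: np.ndarray,
    n_positive: int,
    counts_negative: np.ndarray,
    n_negative: int,
) -> np.ndarray:
    """Per-offset two-tailed hypergeometric p, positive vs negative sets.

    Missing (NaN) where either set is empty.
    """
    kp = np.asarray(counts_positive, dtype=int)
    kn = np.asarray(counts_negative, dtype=int)
    if n_positive == 0 or n_negative == 0:
        return np.full(kp.size, np.nan)
    cache: dict[tuple[int, int], float] = {}
    out = np.empty(kp.size)
    for j in range(kp.size):
        key = (int(kp[j]), int(kn[j]))
        if key not in cache:
            cache[key] = hypergeom_two_tailed(
                key[0], n_positive - key[0], key[1], n_negative - key[1]
            )
        out[j] = cache[key]
    return out


def gc_profile(sequences: Sequence[str], smooth: int = SMOOTH_GC) -> np.ndarray:
    """Smoothed per-offset G/C fraction across aligned sequences.

    Ambiguous bases are excluded from numerator and denominator; A/U
    content is the complement (1 - G/C) on the unambiguous alphabet.
    """
    if not sequences:
        return np.zeros(0)
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("aligned sequences must share their length")
    arr = np.frombuffer(
        "".join(normalize_seq(s) for s in sequences).encode(), dtype="S1"
    ).reshape(len(sequences), length)
    gc = (arr == b"G") | (arr == b"C")
    at = (arr == b"A") | (arr == b"T")
    num = gc.sum(axis=0).astype(float)
    den = (gc | at).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(den > 0, num / den, np.nan)
    return running_mean(freq, smooth)


def motif_distance_distribution(
    pas_sites: Sequence,
    genome: Mapping[str, str],
    peaks: Iterable[PeakRecord] | None = None,
    search_radius: int = SEARCH_RADIUS,
    binding_radius: int = BINDING_RADIUS,
    hexamer: MotifSpec | None = None,
    enhancer: MotifSpec | None = None,
) -> np.ndarray:
    """UGUA-to-hexamer linker lengths upstream of bound reference PAS.

    For each site with proximal binding (>= 1 peak within
    ``binding_radius``; all sites qualify when ``peaks`` is None), the
    upstream ``search_radius`` nt are scanned; the linker is
    start(hexamer nearest the PAS) - end(nearest upstream UGUA). Sites
    lacking either motif contribute nothing. Returns the sorted linker
    lengths (the empirical CDF support).
    """
    hexamer = hexamer or MotifSpec(HEXAMER_PATTERN)
    enhancer = enhancer or MotifSpec(UGUA_PATTERN)
    peak_index = IntervalIndex(peaks) if peaks is not None else None
    linkers = []
    for site in pas_sites:
        chrom, pos, strand = site.chrom, site.position, site.strand
        if peak_index is not None:
            lo = from_offset(pos, strand, -binding_radius)
            hi = from_offset(pos, strand, binding_radius)
            probe = GenomicInterval(chrom, max(0, min(lo, hi)), max(lo, hi) + 1, strand)
            if not peak_index.query(probe, same_strand=True):
                continue
        if strand == "+":
            start = max(0, pos - search_radius)
            region = GenomicInterval(chrom, start, pos, strand) if pos > start else None
        else:
            end = min(len(genome[chrom]), pos + 1 + search_radius)
            region = (
                GenomicInterval(chrom, pos + 1, end, strand) if end > pos + 1 else None
            )
        if region is None:
            continue
        seq = fetch_sequence(genome, region)
        hex_starts = scan_motif(seq, hexamer)
        ugua_starts = scan_motif(seq, enhancer)
        if not hex_starts or not ugua_starts:
            continue
        hex_start = max(hex_starts)  # nearest the PAS
        ugua_ends = [u + len(enhancer.pattern) for u in ugua_starts
                     if u + len(enhancer.pattern) <= hex_start]
        if not ugua_ends:
            continue
        linkers.append(hex_start - max(ugua_ends))
    return np.array(sorted(linkers), dtype=int)
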