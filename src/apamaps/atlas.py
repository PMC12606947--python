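"""Binding-breadth ranking of RBPs and PAS-proximal occupancy profiles."""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    ExpressionTable,
    GenomicInterval,
    IntervalIndex,
    PeakRecord,
    from_offset,
    to_offset,
)

MIN_MEDIAN_TPM = 1.0
PAS_WINDOW = 500
REGION_PRECEDENCE = ("three_prime_utr", "cds", "noncoding_exon", "downstream", "intron")


def select_expressed(
    expr: ExpressionTable, min_median_tpm: float = MIN_MEDIAN_TPM
) -> dict[str, GenomicInterval]:
    """Transcripts whose median control TPM meets the threshold, with 3'UTRs."""
    out = {}
    for tid, tpms in expr.tpm.items():
        if tpms and float(np.median(tpms)) >= min_median_tpm:
            out[tid] = expr.utr[tid]
    return out


def utr_bound_fraction(
    peaks: Iterable[PeakRecord], utrs: Mapping[str, GenomicInterval]
) -> float:
    """Fraction of 3'UTRs with at least one overlapping peak (any replicate)."""
    if not utrs:
        return 0.0
    index = IntervalIndex(peaks)
    bound = sum(1 for utr in utrs.values() if index.query(utr, same_strand=True))
    return bound / len(utrs)


def peak_region_composition(
    peaks: Sequence[PeakRecord],
    regions: Mapping[str, Sequence[GenomicInterval]],
    precedence: Sequence[str] = REGION_PRECEDENCE,
) -> dict[str, float]:
    """Assign each peak to exactly one region class by precedence.

    Peaks overlapping none of the provided regions fall in "unassigned".
    Fractions sum to 1 over the returned keys; an empty peak list yields
    an empty composition.
    """
    if not peaks:
        return {}
    indexes = {
        name: IntervalIndex(ivs) for name, ivs in regions.items()
    }
    order = [r for r in precedence if r in indexes] + [
        r for r in indexes if r not in precedence
    ]
    counts = {name: 0 for name in order}
    counts["unassigned"] = 0
    for peak in peaks:
        for name in order:
            if indexes[name].query(peak.interval, same_strand=True):
                counts[name] += 1
                break
        else:
            counts["unassigned"] += 1
    n = len(peaks)
    return {name: c / n for name, c in counts.items() if c or name != "unassigned"}


def pas_proximal_frequency(
    peaks: Iterable[PeakRecord],
    pas_sites: Sequence[tuple[str, int, str]],
    window: int = PAS_WINDOW,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-offset fraction of PAS covered by >= 1 peak, offsets in [-w, +w].

    ``pas_sites`` are (chrom, position, strand) anchors; offsets are in
    transcript orientation. Returns (offsets, fraction).
    """
    offsets = np.arange(-window, window + 1)
    if not pas_sites:
        return offsets, np.zeros(offsets.size)
    index = IntervalIndex(peaks)
    hits = np.zeros(offsets.size, dtype=float)
    for chrom, pos, strand in pas_sites:
        lo = from_offset(pos, strand, -window)
        hi = from_offset(pos, strand, window)
        start, end = min(lo, hi), max(lo, hi) + 1
        if start < 0:
            start = 0
        probe = GenomicInterval(chrom, start, end, strand)
        covered = np.zeros(offsets.size, dtype=bool)
        for peak in index.query(probe, same_strand=True):
            piv = peak.interval
            o1 = to_offset(pos, strand, piv.start)
            o2 = to_offset(pos, strand, piv.end - 1)
            lo_o, hi_o = min(o1, o2), max(o1, o2)
            lo_i = max(0, lo_o + window)
            hi_i = min(offsets.size, hi_o + window + 1)
            if lo_i < hi_i:
                covered[lo_i:hi_i] = True
        hits += covered
    return offsets, hits / len(pas_sites)


def _footprint(peaks: Iterable[PeakRecord]) -> dict[tuple[str, str], list[tuple[int, int]]]:
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for p in peaks:
        iv = p.interval
        by_key.setdefault((iv.chrom, iv.strand), []).append((iv.start, iv.end))
    merged = {}
    for key, ivs in by_key.items():
        ivs.sort()
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[key] = [tuple(x) for x in out]
    return merged


def _footprint_bp(fp) -> int:
    return sum(e - s for ivs in fp.values() for s, e in ivs)


def _intersection_bp(fa, fb) -> int:
    total = 0
    for key in fa.keys() & fb.keys():
        ia, ib = fa[key], fb[key]
        i = j = 0
        while i < len(ia) and j < len(ib):
            s = max(ia[i][0], ib[j][0])
            e = min(ia[i][1], ib[j][1])
            if s < e:
                total += e - s
            if ia[i][1] < ib[j][1]:
                i += 1
            else:
                j += 1
    return total


def pairwise_peak_jaccard(
    peak_sets: Mapping[str, Sequence[PeakRecord]]
) -> pd.DataFrame:
    """Jaccard index on merged base-pair footprints for every pair of RBPs."""
    names = list(peak_sets)
    fps = {name: _footprint(peak_sets[name]) for name in names}
    sizes = {name: _footprint_bp(fps[name]) for name in names}
    mat = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            inter = _intersection_bp(fps[a], fps[b])
            union = sizes[a] + sizes[b] - inter
            j = inter / union if union else float("nan")
            mat.loc[a, b] = mat.loc[b, a] = j
    return mat
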