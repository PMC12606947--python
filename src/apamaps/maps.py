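"""Positional RNA maps of peak occupancy around regulated PAS.

Profiles are per-offset fractions of events covered by at least one peak,
with 25th/75th percentile bands from 100 event-level bootstrap resamples
and per-offset two-tailed Fisher tests of regulated versus non-changing
event sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval, IntervalIndex, PeakRecord, from_offset, to_offset
from .stats import fisher_exact_two_tailed, neg_log10

WINDOW = 300
N_BOOT = 100
PERCENTILES = (25.0, 75.0)


@dataclass
class PositionalProfile:
    anchor: str
    offsets: np.ndarray
    fraction: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray
    n_events: int
    p: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {
            "offset": self.offsets,
            "fraction": self.fraction,
            "band_low": self.band_low,
            "band_high": self.band_high,
        }
        if self.p is not None:
            data["p"] = self.p
        return pd.DataFrame(data)


def event_window_matrix(
    events: pd.DataFrame,
    peaks: Iterable[PeakRecord],
    anchor: str,
    window: int = WINDOW,
) -> np.ndarray:
    """Binary event x offset matrix of peak coverage around an anchor.

    ``events`` must carry chrom, strand, ppas, dpas columns; ``anchor`` is
    "pPAS" or "dPAS". Entry (i, j) is 1 iff >= 1 peak covers offset
    j - window (transcript orientation) from event i's anchor.
    """
    col = {"pPAS": "ppas", "dPAS": "dpas"}[anchor]
    index = IntervalIndex(peaks)
    n_off = 2 * window + 1
    mat = np.zeros((len(events), n_off), dtype=np.uint8)
    for i, row in enumerate(events.itertuples(index=False)):
        pos = int(getattr(row, col))
        strand = row.strand
        lo = from_offset(pos, strand, -window)
        hi = from_offset(pos, strand, window)
        start, end = max(0, min(lo, hi)), max(lo, hi) + 1
        probe = GenomicInterval(row.chrom, start, end, strand)
        for peak in index.query(probe, same_strand=True):
            piv = peak.interval
            o1 = to_offset(pos, strand, piv.start)
            o2 = to_offset(pos, strand, piv.end - 1)
            lo_o, hi_o = min(o1, o2), max(o1, o2)
            lo_i = max(0, lo_o + window)
            hi_i = min(n_off, hi_o + window + 1)
            if lo_i < hi_i:
                mat[i, lo_i:hi_i] = 1
    return mat


def fraction_with_bootstrap(
    matrix: np.ndarray,
    anchor: str = "dPAS",
    n_boot: int = N_BOOT,
    percentiles: tuple[float, float] = PERCENTILES,
    seed: int = 0,
) -> PositionalProfile:
    """Per-offset bound fraction with a bootstrap percentile band.

    Events (rows) are resampled with replacement ``n_boot`` times; the band
    is the stated percentiles of the per-resample means. Deterministic
    under a fixed seed.
    """
    matrix = np.asarray(matrix)
    n_events, n_off = matrix.shape
    window = (n_off - 1) // 2
    offsets = np.arange(-window, n_off - window)
    fraction = matrix.mean(axis=0) if n_events else np.full(n_off, np.nan)
    rng = np.random.default_rng(seed)
    if n_events:
        idx = rng.integers(0, n_events, size=(n_boot, n_events))
        boot_means = matrix[idx].mean(axis=1)  # n_boot x n_off
        band_low = np.percentile(boot_means, percentiles[0], axis=0)
        band_high = np.percentile(boot_means, percentiles[1], axis=0)
    else:
        band_low = band_high = np.full(n_off, np.nan)
    return PositionalProfile(anchor, offsets, fraction, band_low, band_high, n_events)


def positional_fisher(
    matrix_regulated: np.ndarray, matrix_control: np.ndarray
) -> np.ndarray:
    """Per-offset two-tailed Fisher p of bound fractions, regulated vs control.

    Offsets where either event set is empty give NaN.
    """
    mr = np.asarray(matrix_regulated)
    mc = np.asarray(matrix_control)
    n_off = mr.shape[1] if mr.ndim == 2 else mc.shape[1]
    if mr.shape[0] == 0 or mc.shape[0] == 0:
        return np.full(n_off, np.nan)
    if mr.shape[1] != mc.shape[1]:
        raise ValueError("matrices must share the offset axis")
    kr = mr.sum(axis=0).astype(int)
    kc = mc.sum(axis=0).astype(int)
    nr, nc = mr.shape[0], mc.shape[0]
    cache: dict[tuple[int, int], float] = {}
    out = np.empty(n_off)
    for j in range(n_off):
        key = (int(kr[j]), int(kc[j]))
        if key not in cache:
            cache[key] = fisher_exact_two_tailed(key[0], nr - key[0], key[1], nc - key[1])
        out[j] = cache[key]
    return out


def enrichment_heatmap_rows(
    profiles: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
) -> pd.DataFrame:
    """Signed -log10(p) rows per RBP, ordered by peak significance.

    ``profiles`` maps rbp -> (p values, regulated fraction, control
    fraction); the sign is positive where the regulated set is more bound
    and negative where it is depleted.
    """
    rows = {}
    for rbp, (p, frac_reg, frac_ctl) in profiles.items():
        signed = np.array([neg_log10(v) for v in p])
        sign = np.where(frac_reg >= frac_ctl, 1.0, -1.0)
        rows[rbp] = signed * sign
    df = pd.DataFrame(rows).T
    order = df.abs().max(axis=1).sort_values(ascending=False).index
    return df.loc[order]
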