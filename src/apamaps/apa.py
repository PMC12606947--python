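"""APA change calling from replicate usage tables and dPDUI classification.

Two routes to regulated-event sets are implemented: replicate-consistency
calls on 3'-end cluster usage (10% shift in 2 of 3 replicate pairs, no
opposite comparison), and thresholding of a DaPars-style dPDUI table
(|dPDUI| >= 0.20 with adjusted p < 0.05; non-changing |dPDUI| < 0.05 with
p > 0.05). dPDUI follows the control-minus-knockdown convention, so
positive values mean depletion shifts usage toward the proximal site
(the protein normally lengthens the 3'UTR).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import fisher_exact_two_tailed

LENGTHENED = "lengthened_by_RBP"
SHORTENED = "shortened_by_RBP"
NON_CHANGING = "non_changing"
UNCLASSIFIED = "unclassified"

CHANGE_THRESH = 0.20
NULL_THRESH = 0.05
ALPHA = 0.05

DELTA_THRESH = 0.10
N_SUPPORT = 2
OPPOSITE_TOLERANCE = 0.0
NONCHANGE_MIN_READS = 10
NONCHANGE_MAX_DELTA = 0.05


@dataclass
class ApaCall:
    """Per-cluster regulation call from replicate usage deltas (KD - control)."""

    terminal_exon_id: str
    cluster_id: str
    deltas: tuple[float, ...]
    status: str  # increased | decreased | not_called
    compartment: str = "whole"


def classify_dpdui(
    table: pd.DataFrame,
    change_thresh: float = CHANGE_THRESH,
    null_thresh: float = NULL_THRESH,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Label each terminal exon from its dPDUI and adjusted p.

    dPDUI >= +change_thresh & p < alpha -> lengthened_by_RBP;
    dPDUI <= -change_thresh & p < alpha -> shortened_by_RBP;
    |dPDUI| < null_thresh & p > alpha   -> non_changing; else unclassified.
    Rows with missing p are skipped with a warning.
    """
    df = table.copy()
    missing = df["adjusted_p"].isna()
    if missing.any():
        warnings.warn(f"skipping {int(missing.sum())} rows with missing adjusted p")
        df = df[~missing]
    d = df["dpdui"].to_numpy(dtype=float)
    p = df["adjusted_p"].to_numpy(dtype=float)
    label = np.full(len(df), UNCLASSIFIED, dtype=object)
    label[(d >= change_thresh) & (p < alpha)] = LENGTHENED
    label[(d <= -change_thresh) & (p < alpha)] = SHORTENED
    label[(np.abs(d) < null_thresh) & (p > alpha)] = NON_CHANGING
    df = df.assign(label=label)
    return df


def _deltas(
    usage_row: pd.Series, pairing: Sequence[tuple[str, str]]
) -> np.ndarray:
    for kd, ctl in pairing:
        if kd not in usage_row.index or ctl not in usage_row.index:
            raise ValueError(f"unpaired sample in pairing ({kd}, {ctl})")
    return np.array([usage_row[kd] - usage_row[ctl] for kd, ctl in pairing])


def call_pas_changes(
    usage: pd.DataFrame,
    pairing: Sequence[tuple[str, str]],
    delta_thresh: float = DELTA_THRESH,
    n_support: int = N_SUPPORT,
    opposite_tolerance: float = OPPOSITE_TOLERANCE,
    compartment: str = "whole",
) -> list[ApaCall]:
    """Call per-cluster usage changes from replicate KD-control pairs.

    A cluster is "increased" when at least ``n_support`` deltas are
    >= +delta_thresh and no delta is below -opposite_tolerance
    ("decreased" symmetrically); anything else is not_called. Deltas
    undefined in either member of a pair are ignored, but at least
    ``n_support`` defined pairs are required for a call.
    """
    calls = []
    for (exon_id, cluster_id), row in usage.iterrows():
        deltas = _deltas(row, pairing)
        defined = deltas[~np.isnan(deltas)]
        status = "not_called"
        if defined.size >= n_support:
            n_up = int(np.sum(defined >= delta_thresh))
            n_down = int(np.sum(defined <= -delta_thresh))
            any_neg = bool(np.any(defined < -opposite_tolerance))
            any_pos = bool(np.any(defined > opposite_tolerance))
            if n_up >= n_support and not any_neg:
                status = "increased"
            elif n_down >= n_support and not any_pos:
                status = "decreased"
        calls.append(ApaCall(exon_id, cluster_id, tuple(deltas), status, compartment))
    return calls


def call_nonchanging(
    usage: pd.DataFrame,
    counts: pd.DataFrame,
    pairing: Sequence[tuple[str, str]],
    min_reads: int = NONCHANGE_MIN_READS,
    max_delta: float = NONCHANGE_MAX_DELTA,
) -> list[str]:
    """Confidently non-changing terminal exons.

    An exon qualifies iff every sample's exon read total is >= min_reads
    and no cluster's usage changes by more than max_delta in any replicate
    pair.
    """
    samples = {s for pair in pairing for s in pair}
    exon_totals = counts[sorted(samples)].groupby(level="terminal_exon_id").sum()
    out = []
    for exon_id, totals in exon_totals.iterrows():
        if (totals < min_reads).any():
            continue
        rows = usage.xs(exon_id, level="terminal_exon_id", drop_level=False)
        ok = True
        for _, row in rows.iterrows():
            deltas = _deltas(row, pairing)
            if np.any(np.isnan(deltas)) or np.any(np.abs(deltas) > max_delta):
                ok = False
                break
        if ok:
            out.append(exon_id)
    return out


def exon_direction(calls: Iterable[ApaCall]) -> dict[str, str]:
    """Collapse cluster-level calls to an exon-level lengthening direction.

    The 3'-most called cluster decides (cluster ids are ordered 5'->3'
    within an exon): distal usage increased on knockdown means the protein
    normally shortens the 3'UTR, decreased means it lengthens it.
    """
    by_exon: dict[str, list[ApaCall]] = {}
    for call in calls:
        if call.status != "not_called":
            by_exon.setdefault(call.terminal_exon_id, []).append(call)
    out = {}
    for exon_id, group in by_exon.items():
        group.sort(key=lambda c: int(c.cluster_id.rsplit(":", 1)[1]))
        distal = group[-1]
        out[exon_id] = LENGTHENED if distal.status == "decreased" else SHORTENED
    return out


def compare_compartments(
    nuclear_calls: Iterable[ApaCall],
    cytoplasmic_calls: Iterable[ApaCall],
    nuclear_nonchanging: Iterable[str],
    cytoplasmic_nonchanging: Iterable[str],
) -> dict[str, list[str]]:
    """Shared vs compartment-specific changing terminal exons.

    shared: significant with the same direction in both compartments;
    X-specific: significant in X and confidently non-changing in the other.
    Exons significant in one compartment but merely unobserved in the other
    fall in neither list.
    """
    nuc = exon_direction(nuclear_calls)
    cyt = exon_direction(cytoplasmic_calls)
    nuc_nc = set(nuclear_nonchanging)
    cyt_nc = set(cytoplasmic_nonchanging)
    shared = sorted(g for g in nuc.keys() & cyt.keys() if nuc[g] == cyt[g])
    cyt_specific = sorted(g for g in cyt.keys() & nuc_nc if g not in nuc)
    nuc_specific = sorted(g for g in nuc.keys() & cyt_nc if g not in cyt)
    return {
        "shared": shared,
        "cytoplasm_specific": cyt_specific,
        "nucleus_specific": nuc_specific,
    }


def overlap_stats(
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe: Iterable[str],
    directions_a: Mapping[str, str] | None = None,
    directions_b: Mapping[str, str] | None = None,
) -> tuple[float, float, float]:
    """Fisher p, Jaccard index, and same-direction fraction of two gene sets.

    Fisher's exact test (two-tailed) is computed on membership over the
    jointly quantified universe; the direction fraction is over the
    intersection (NaN when directions are absent or the intersection is
    empty).
    """
    a, b, u = set(set_a), set(set_b), set(universe)
    if not a <= u or not b <= u:
        raise ValueError("sets must be subsets of the universe")
    inter = a & b
    union = a | b
    n11 = len(inter)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = len(u) - len(union)
    fisher_p = fisher_exact_two_tailed(n11, n10, n01, n00)
    jaccard = len(inter) / len(union) if union else float("nan")
    if directions_a is None or directions_b is None or not inter:
        same_dir = float("nan")
    else:
        same_dir = sum(
            1 for g in inter if directions_a.get(g) == directions_b.get(g)
        ) / len(inter)
    return fisher_p, jaccard, same_dir
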