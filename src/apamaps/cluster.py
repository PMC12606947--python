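"""3'-end cluster calling, PAS assignment, and artifact filtering.

Clusters are maximal runs of positions whose pooled (all-sample) 3'-end
read count exceeds a per-position threshold; the PAS of a cluster is its
highest-coverage position (3'-most on ties, transcript orientation).
Internal-priming artifacts are removed by two genomic-adenosine heuristics,
and clusters are further required to contain a PAS hexamer and to match a
reference site catalogue before entering usage analysis.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    CoverageTrack,
    GenomicInterval,
    IntervalIndex,
    PasReferenceSite,
    TerminalExon,
    downstream_sequence,
    fetch_sequence,
)

# filter flags
FAIL_LOW_TOTAL = "fail_low_total"
FAIL_CONSECUTIVE_A = "fail_consecutive_A"
FAIL_A_RICH_WINDOW = "fail_A_rich_window"
FAIL_NO_HEXAMER = "fail_no_hexamer"
FAIL_NOT_IN_REFERENCE = "fail_not_in_reference"

HEXAMERS = ("AATAAA", "ATTAAA")

MIN_PER_POSITION = 10
MIN_TOTAL = 20
MAX_CONSECUTIVE_A = 6  # more than this many downstream As flags the cluster
A_WINDOW_LEN = 10
MAX_A_IN_WINDOW = 7


@dataclass
class PasCluster:
    """A called 3'-end cluster with PAS position and per-sample counts."""

    interval: GenomicInterval
    total: int
    pas_position: int | None = None
    counts: dict[str, int] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)
    terminal_exon_id: str | None = None
    cluster_id: str | None = None

    @property
    def passed(self) -> bool:
        return not self.flags


def combine_tracks(tracks: Iterable[CoverageTrack]) -> dict[tuple[str, str], Counter]:
    """Sum per-position counts across samples."""
    combined: dict[tuple[str, str], Counter] = {}
    for track in tracks:
        for key, counts in track.data.items():
            combined.setdefault(key, Counter()).update(counts)
    return combined


def call_clusters(
    combined: Mapping[tuple[str, str], Counter],
    min_per_position: int = MIN_PER_POSITION,
    min_total: int = MIN_TOTAL,
    keep_filtered: bool = False,
) -> list[PasCluster]:
    """Merge contiguous positions with count > ``min_per_position``.

    Clusters whose pooled count is < ``min_total`` are dropped, or flagged
    ``fail_low_total`` when ``keep_filtered`` is set.
    """
    clusters = []
    for (chrom, strand), counts in sorted(combined.items()):
        positions = sorted(p for p, c in counts.items() if c > min_per_position)
        if not positions:
            continue
        run_start = prev = positions[0]
        run_total = counts[run_start]
        for pos in positions[1:]:
            if pos == prev + 1:
                run_total += counts[pos]
                prev = pos
                continue
            _emit(clusters, chrom, strand, run_start, prev, run_total,
                  min_total, keep_filtered)
            run_start = prev = pos
            run_total = counts[pos]
        _emit(clusters, chrom, strand, run_start, prev, run_total,
              min_total, keep_filtered)
    return clusters


def _emit(clusters, chrom, strand, start, last, total, min_total, keep_filtered):
    cluster = PasCluster(GenomicInterval(chrom, start, last + 1, strand), total)
    if total < min_total:
        if not keep_filtered:
            return
        cluster.flags.add(FAIL_LOW_TOTAL)
    clusters.append(cluster)


def assign_pas(cluster: PasCluster, combined: Mapping[tuple[str, str], Counter]) -> int:
    """Highest-coverage position within the cluster; 3'-most on ties."""
    iv = cluster.interval
    counts = combined[(iv.chrom, iv.strand)]
    positions = range(iv.start, iv.end)
    best_pos = None
    best_count = -1
    # walk in transcript 5'->3' order; >= keeps the 3'-most position on ties
    for pos in positions if iv.strand == "+" else reversed(positions):
        c = counts.get(pos, 0)
        if c >= best_count:
            best_count = c
            best_pos = pos
    cluster.pas_position = best_pos
    return best_pos


def attach_sample_counts(clusters: Sequence[PasCluster], tracks: Iterable[CoverageTrack]) -> None:
    """Fill per-sample read counts for each cluster."""
    tracks = list(tracks)
    for cluster in clusters:
        iv = cluster.interval
        for track in tracks:
            counts = track.data.get((iv.chrom, iv.strand), Counter())
            cluster.counts[track.sample_id] = sum(
                counts.get(p, 0) for p in range(iv.start, iv.end)
            )


# ---------------------------------------------------------------------------
# filters

def filter_internal_priming(cluster: PasCluster, genome: Mapping[str, str]) -> set[str]:
    """Internal-priming heuristics on genomically encoded adenosines.

    ``fail_consecutive_A``: the transcript-orientation sequence immediately
    downstream of the PAS begins with more than 6 consecutive A.
    ``fail_A_rich_window``: the 10 nt immediately downstream of the cluster
    3' boundary contain more than 7 A.
    """
    if cluster.pas_position is None:
        raise ValueError("assign_pas before filtering")
    iv = cluster.interval
    flags = set()
    down = downstream_sequence(
        genome, iv.chrom, iv.strand, cluster.pas_position, MAX_CONSECUTIVE_A + 1
    )
    run = len(down) - len(down.lstrip("A"))
    if run > MAX_CONSECUTIVE_A:
        flags.add(FAIL_CONSECUTIVE_A)
    # cluster 3' boundary: first base after the 3'-most cluster position
    boundary = iv.end - 1 if iv.strand == "+" else iv.start
    window = downstream_sequence(genome, iv.chrom, iv.strand, boundary, A_WINDOW_LEN)
    if window.count("A") > MAX_A_IN_WINDOW:
        flags.add(FAIL_A_RICH_WINDOW)
    cluster.flags |= flags
    return flags


def filter_hexamer(
    cluster: PasCluster, genome: Mapping[str, str], flank_upstream: int = 0
) -> set[str]:
    """Require a top PAS hexamer (AATAAA/ATTAAA in DNA) in the cluster.

    ``flank_upstream`` widens the search on the transcript-orientation 5'
    side; 0 searches the strict cluster interval. The hexamer typically
    ends 10-20 nt upstream of cleavage, so narrow clusters may need the
    flank to cover the canonical geometry.
    """
    iv = cluster.interval
    if iv.strand == "+":
        start = max(0, iv.start - flank_upstream)
        region = GenomicInterval(iv.chrom, start, iv.end, iv.strand)
    else:
        end = min(len(genome[iv.chrom]), iv.end + flank_upstream)
        region = GenomicInterval(iv.chrom, iv.start, end, iv.strand)
    seq = fetch_sequence(genome, region)
    if not any(h in seq for h in HEXAMERS):
        cluster.flags.add(FAIL_NO_HEXAMER)
        return {FAIL_NO_HEXAMER}
    return set()


def filter_reference(
    cluster: PasCluster, reference: Sequence[PasReferenceSite], slack: int = 0
) -> set[str]:
    """Require a same-strand reference site within [start - slack, end + slack)."""
    iv = cluster.interval
    lo, hi = iv.start - slack, iv.end + slack
    for site in reference:
        if site.chrom == iv.chrom and site.strand == iv.strand and lo <= site.position < hi:
            return set()
    cluster.flags.add(FAIL_NOT_IN_REFERENCE)
    return {FAIL_NOT_IN_REFERENCE}


def apply_filters(
    clusters: Sequence[PasCluster],
    genome: Mapping[str, str],
    reference: Sequence[PasReferenceSite] | None = None,
    reference_slack: int = 0,
    hexamer_flank_upstream: int = 0,
) -> pd.DataFrame:
    """Run internal-priming, hexamer, and reference filters, accumulating flags.

    Returns the filter funnel: clusters surviving after each stage, in the
    order low-total -> internal priming -> hexamer -> reference.
    """
    funnel = [("called", len(clusters))]
    alive = [c for c in clusters if FAIL_LOW_TOTAL not in c.flags]
    funnel.append(("min_total", len(alive)))
    for c in clusters:
        filter_internal_priming(c, genome)
    alive = [c for c in alive if not c.flags]
    funnel.append(("internal_priming", len(alive)))
    for c in clusters:
        filter_hexamer(c, genome, flank_upstream=hexamer_flank_upstream)
    alive = [c for c in alive if not c.flags]
    funnel.append(("hexamer", len(alive)))
    if reference is not None:
        # index reference sites for speed on larger runs
        ref_index = IntervalIndex(
            GenomicInterval(s.chrom, s.position, s.position + 1, s.strand)
            for s in reference
        )
        for c in clusters:
            iv = c.interval
            probe = GenomicInterval(
                iv.chrom, max(0, iv.start - reference_slack), iv.end + reference_slack,
                iv.strand,
            )
            if not ref_index.query(probe, same_strand=True):
                c.flags.add(FAIL_NOT_IN_REFERENCE)
        alive = [c for c in alive if not c.flags]
        funnel.append(("reference", len(alive)))
    return pd.DataFrame(funnel, columns=["stage", "clusters"])


# ---------------------------------------------------------------------------
# terminal-exon assignment and relative usage

def assign_terminal_exon(
    clusters: Sequence[PasCluster], exons: Sequence[TerminalExon]
) -> list[PasCluster]:
    """Assign each cluster to the same-strand terminal exon containing its PAS.

    When the PAS falls inside several overlapping same-strand exons, the
    exon whose annotated 3' end lies nearest downstream wins. Returns the
    assigned clusters (unassigned ones keep terminal_exon_id None).
    """
    index = IntervalIndex(exons)
    assigned = []
    for cluster in clusters:
        if cluster.pas_position is None:
            raise ValueError("assign_pas before exon assignment")
        iv = cluster.interval
        probe = GenomicInterval(iv.chrom, cluster.pas_position,
                                cluster.pas_position + 1, iv.strand)
        hits = index.query(probe, same_strand=True)
        if not hits:
            continue

        def dist_to_3p(exon: TerminalExon) -> int:
            e = exon.interval
            return (e.end - 1 - cluster.pas_position if iv.strand == "+"
                    else cluster.pas_position - e.start)

        best = min(hits, key=dist_to_3p)
        cluster.terminal_exon_id = best.gene_id
        assigned.append(cluster)
    return assigned


def name_clusters(clusters: Sequence[PasCluster]) -> None:
    """Assign ids exon:index with index in transcript 5'->3' order."""
    by_exon: dict[str, list[PasCluster]] = {}
    for c in clusters:
        if c.terminal_exon_id is None:
            continue
        by_exon.setdefault(c.terminal_exon_id, []).append(c)
    for exon_id, group in by_exon.items():
        group.sort(
            key=lambda c: c.pas_position,
            reverse=group[0].interval.strand == "-",
        )
        for i, c in enumerate(group):
            c.cluster_id = f"{exon_id}:{i}"


def compute_relative_usage(
    clusters: Sequence[PasCluster], sample_ids: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample relative usage of each cluster within its terminal exon.

    Returns (usage, counts) DataFrames indexed by (terminal_exon_id,
    cluster_id). Usage is cluster count over the exon total for that
    sample; exon-sample totals of zero give missing values, not zeros.
    """
    rows = []
    idx = []
    for c in clusters:
        if c.terminal_exon_id is None or c.cluster_id is None:
            continue
        idx.append((c.terminal_exon_id, c.cluster_id))
        rows.append([c.counts.get(s, 0) for s in sample_ids])
    counts = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(idx, names=["terminal_exon_id", "cluster_id"])
        if idx else pd.MultiIndex.from_arrays([[], []], names=["terminal_exon_id", "cluster_id"]),
        columns=list(sample_ids),
        dtype=float,
    )
    counts = counts.sort_index()
    exon_totals = counts.groupby(level="terminal_exon_id").transform("sum")
    usage = counts / exon_totals.where(exon_totals > 0, np.nan)
    return usage, counts
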