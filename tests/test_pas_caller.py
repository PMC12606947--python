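"""Cluster calling, PAS assignment, artifact filters, exon assignment, and
relative usage — examples plus a brute-force oracle over random tracks."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from apamaps.cluster import (
    FAIL_A_RICH_WINDOW,
    FAIL_CONSECUTIVE_A,
    FAIL_NO_HEXAMER,
    FAIL_NOT_IN_REFERENCE,
    PasCluster,
    assign_pas,
    assign_terminal_exon,
    call_clusters,
    compute_relative_usage,
    filter_hexamer,
    filter_internal_priming,
    filter_reference,
    name_clusters,
)
from apamaps.core import GenomicInterval, PasReferenceSite, TerminalExon


def _combined(counts: dict[int, int], strand: str = "+"):
    return {("c", strand): Counter(counts)}


def _cluster(start, end, strand="+", pas=None, total=100):
    c = PasCluster(GenomicInterval("c", start, end, strand), total)
    c.pas_position = pas
    return c


# ---------------------------------------------------------------------------
# brute-force oracle used for the cluster/PAS equivalence checks

def brute_force_clusters(counts: dict[int, int], strand: str, min_pp=10, min_total=20):
    """Per-position scan: runs of count > min_pp, then argmax with the
    3'-most tie break."""
    if not counts:
        return []
    hi = max(counts) + 2
    arr = np.zeros(hi, dtype=int)
    for p, v in counts.items():
        arr[p] = v
    above = arr > min_pp
    out = []
    i = 0
    while i < hi:
        if above[i]:
            j = i
            while j < hi and above[j]:
                j += 1
            total = int(arr[i:j].sum())
            if total >= min_total:
                sub = arr[i:j]
                best = sub.max()
                ties = [i + k for k in range(j - i) if sub[k] == best]
                pas = max(ties) if strand == "+" else min(ties)
                out.append((i, j, total, pas))
            i = j
        else:
            i += 1
    return out


def call_and_assign(counts, strand, min_pp=10, min_total=20):
    combined = _combined(counts, strand)
    clusters = call_clusters(combined, min_pp, min_total)
    return [
        (c.interval.start, c.interval.end, c.total, assign_pas(c, combined))
        for c in clusters
    ]


class TestCallClusters:
    def test_worked_example(self):
        counts = dict(zip(range(100, 111), [5, 12, 15, 20, 11, 9, 13, 14, 11, 0, 30]))
        got = call_and_assign(counts, "+")
        assert [(s, e, t) for s, e, t, _ in got] == [
            (101, 105, 58), (106, 109, 38), (110, 111, 30)]

    def test_all_below_threshold(self):
        assert call_clusters(_combined({100: 10, 101: 9})) == []

    def test_single_position(self):
        (c,) = call_clusters(_combined({100: 30}))
        assert (c.interval.start, c.interval.end, c.total) == (100, 101, 30)

    def test_low_total_dropped_or_flagged(self):
        assert call_clusters(_combined({100: 11})) == []
        (c,) = call_clusters(_combined({100: 11}), keep_filtered=True)
        assert "fail_low_total" in c.flags

    def test_matches_brute_force_on_random_tracks(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            length = int(rng.integers(10, 1000))
            strand = "+" if rng.random() < 0.5 else "-"
            n_pos = int(rng.integers(1, length))
            positions = rng.choice(length, size=n_pos, replace=False)
            counts = {int(p): int(rng.integers(0, 40)) for p in positions}
            assert call_and_assign(counts, strand) == brute_force_clusters(counts, strand)


class TestAssignPas:
    def test_argmax(self):
        counts = {101: 12, 102: 15, 103: 20, 104: 11}
        c = _cluster(101, 105)
        assert assign_pas(c, _combined(counts)) == 103

    def test_tie_three_prime_most_plus(self):
        c = _cluster(200, 202)
        assert assign_pas(c, _combined({200: 15, 201: 15})) == 201

    def test_tie_three_prime_most_minus(self):
        c = _cluster(200, 202, strand="-")
        assert assign_pas(c, _combined({200: 15, 201: 15}, "-")) == 200


class TestInternalPriming:
    def test_seven_consecutive_a_flags(self):
        genome = {"c": "G" * 10 + "AAAAAAAG" + "C" * 20}
        c = _cluster(5, 10, pas=9)  # downstream starts at 10: AAAAAAA (7)
        assert filter_internal_priming(c, genome) == {FAIL_CONSECUTIVE_A}

    def test_six_a_passes_but_window_fails(self):
        # downstream of PAS: AAAAAAG (6 consecutive) passes the run rule;
        # the 10 nt after the cluster boundary hold 9 A > 7
        genome = {"c": "G" * 10 + "AAAAAAGAAA" + "A" * 5 + "C" * 20}
        c = _cluster(5, 10, pas=9)
        assert filter_internal_priming(c, genome) == {FAIL_A_RICH_WINDOW}

    def test_gc_downstream_clean(self):
        genome = {"c": "A" * 10 + "GCGCGCGCGC" + "G" * 10}
        c = _cluster(5, 10, pas=9)
        assert filter_internal_priming(c, genome) == set()

    def test_minus_strand_reads_transcript_orientation(self):
        # minus-strand downstream of PAS at 20 = genomic 13..19 reversed;
        # genomic T run reads as A run on the transcript
        genome = {"c": "G" * 13 + "TTTTTTT" + "G" * 20}
        c = _cluster(20, 25, strand="-", pas=20)
        assert FAIL_CONSECUTIVE_A in filter_internal_priming(c, genome)


class TestHexamerAndReference:
    def test_hexamer_variants(self):
        c1 = _cluster(5, 15, pas=10)
        assert filter_hexamer(c1, {"c": "GGGGG" + "AATAAA" + "GGGGGGGGGG"}) == set()
        c2 = _cluster(5, 15, pas=10)
        assert filter_hexamer(c2, {"c": "GGGGG" + "ATTAAA" + "GGGGGGGGGG"}) == set()
        c3 = _cluster(5, 15, pas=10)
        assert filter_hexamer(c3, {"c": "GGGGG" + "AAGAAA" + "GGGGGGGGGG"}) == {
            FAIL_NO_HEXAMER}

    def test_hexamer_upstream_flank(self):
        genome = {"c": "AATAAA" + "G" * 30}
        strict = _cluster(10, 20, pas=15)
        assert filter_hexamer(strict, genome) == {FAIL_NO_HEXAMER}
        flanked = _cluster(10, 20, pas=15)
        assert filter_hexamer(flanked, genome, flank_upstream=10) == set()

    def test_reference_inside_and_slack(self):
        ref = [PasReferenceSite("c", 102, "+")]
        assert filter_reference(_cluster(100, 110), ref) == set()
        far = [PasReferenceSite("c", 160, "+")]
        assert filter_reference(_cluster(100, 110), far) == {FAIL_NOT_IN_REFERENCE}
        near = [PasReferenceSite("c", 114, "+")]
        assert filter_reference(_cluster(100, 110), near, slack=10) == set()
        wrong_strand = [PasReferenceSite("c", 102, "-")]
        assert filter_reference(_cluster(100, 110), wrong_strand) == {
            FAIL_NOT_IN_REFERENCE}


class TestExonAssignmentAndUsage:
    exons = [
        TerminalExon("GENE1", GenomicInterval("c", 100, 500, "+", id="GENE1")),
        TerminalExon("GENE2", GenomicInterval("c", 300, 700, "+", id="GENE2")),
    ]

    def test_assignment_and_intergenic(self):
        inside = _cluster(150, 160, pas=155)
        outside = _cluster(800, 810, pas=805)
        assigned = assign_terminal_exon([inside, outside], self.exons)
        assert assigned == [inside]
        assert inside.terminal_exon_id == "GENE1"
        assert outside.terminal_exon_id is None

    def test_overlap_resolved_to_nearest_three_prime_end(self):
        c = _cluster(400, 410, pas=405)
        assign_terminal_exon([c], self.exons)
        assert c.terminal_exon_id == "GENE1"  # end 500 closer than 700

    def test_relative_usage(self):
        c1 = _cluster(150, 160, pas=155)
        c2 = _cluster(300, 310, pas=305)
        for c in (c1, c2):
            c.terminal_exon_id = "GENE1"
        c1.cluster_id, c2.cluster_id = "GENE1:0", "GENE1:1"
        c1.counts = {"s1": 30, "s2": 0}
        c2.counts = {"s1": 70, "s2": 0}
        usage, counts = compute_relative_usage([c1, c2], ["s1", "s2"])
        assert usage.loc[("GENE1", "GENE1:0"), "s1"] == pytest.approx(0.30)
        assert usage.loc[("GENE1", "GENE1:1"), "s1"] == pytest.approx(0.70)
        # zero exon total: missing, not zero
        assert usage["s2"].isna().all()

    def test_single_cluster_usage_one(self):
        c = _cluster(150, 160, pas=155)
        c.terminal_exon_id, c.cluster_id = "GENE1", "GENE1:0"
        c.counts = {"s1": 12}
        usage, _ = compute_relative_usage([c], ["s1"])
        assert usage.loc[("GENE1", "GENE1:0"), "s1"] == 1.0

    def test_usage_rows_sum_to_one(self, default_run):
        usage = default_run["usage"]
        sums = usage.groupby(level="terminal_exon_id").sum()
        defined = ~usage.isna().groupby(level="terminal_exon_id").any()
        assert np.allclose(sums.to_numpy()[defined.to_numpy()], 1.0, atol=1e-12)

    def test_cluster_naming_transcript_order(self):
        plus1 = _cluster(150, 160, pas=155)
        plus2 = _cluster(300, 310, pas=305)
        for c in (plus1, plus2):
            c.terminal_exon_id = "GENE1"
        minus1 = _cluster(150, 160, strand="-", pas=155)
        minus2 = _cluster(300, 310, strand="-", pas=305)
        for c in (minus1, minus2):
            c.terminal_exon_id = "GENEM"
        name_clusters([plus2, plus1, minus1, minus2])
        assert (plus1.cluster_id, plus2.cluster_id) == ("GENE1:0", "GENE1:1")
        # minus strand: larger coordinate is more 5'
        assert (minus2.cluster_id, minus1.cluster_id) == ("GENEM:0", "GENEM:1")
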