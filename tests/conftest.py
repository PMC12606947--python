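"""Shared fixtures: a session-scoped default simulation run through the
cluster caller, reused by the filter/recovery tests."""

from __future__ import annotations

import pytest

from apamaps.cluster import (
    apply_filters,
    assign_pas,
    assign_terminal_exon,
    attach_sample_counts,
    call_clusters,
    combine_tracks,
    compute_relative_usage,
    name_clusters,
)
from apamaps.simulate import SimConfig, simulate_genome, simulate_three_prime_reads


@pytest.fixture(scope="session")
def default_run():
    """Default cohort (200 genes, 50 regulated, shift 0.30, seed 1) taken
    through cluster calling, filtering, and usage computation."""
    cfg = SimConfig(seed=1)
    genome, exons, reference, truth = simulate_genome(cfg)
    tracks = simulate_three_prime_reads(cfg, truth)
    combined = combine_tracks(tracks)
    clusters = call_clusters(combined, keep_filtered=True)
    for c in clusters:
        assign_pas(c, combined)
    funnel = apply_filters(clusters, genome, reference, hexamer_flank_upstream=30)
    passed = [c for c in clusters if c.passed]
    assigned = assign_terminal_exon(passed, exons)
    name_clusters(assigned)
    attach_sample_counts(assigned, tracks)
    usage, counts = compute_relative_usage(assigned, cfg.sample_ids())
    return {
        "cfg": cfg,
        "genome": genome,
        "exons": exons,
        "reference": reference,
        "truth": truth,
        "tracks": tracks,
        "combined": combined,
        "clusters": clusters,
        "assigned": assigned,
        "usage": usage,
        "counts": counts,
        "funnel": funnel,
    }
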