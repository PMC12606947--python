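"""IUPAC motif scanning, sliding-window frequency maps, GC profiles, and
UGUA-to-hexamer spacing."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apamaps.core import GenomicInterval, PasReferenceSite, PeakRecord
from apamaps.motifs import (
    IUPAC,
    MotifSpec,
    gc_profile,
    motif_distance_distribution,
    positional_hypergeom,
    running_mean,
    scan_motif,
    window_frequency,
    window_match_counts,
)


class TestScanMotif:
    def test_hexamer_examples(self):
        spec = MotifSpec("AWUAAA")
        assert scan_motif("xxAATAAAxx".replace("x", "G"), spec) == [2]
        assert scan_motif("GGATTAAAGG", spec) == [2]
        assert scan_motif("GGAAGAAAGG", spec) == []

    def test_reverse_complement_orientation(self):
        # revcomp(AWUAAA) = UUUAWU -> TTTAWT; TTTATT matches at 0
        spec = MotifSpec("AWUAAA", "reverse_complement")
        assert spec.scan_pattern == "TTTAWT"
        assert scan_motif("TTTATT", spec) == [0]
        assert MotifSpec("UGUA", "reverse_complement").scan_pattern == "TACA"

    def test_overlapping_matches(self):
        assert scan_motif("TGTGTA", MotifSpec("TGTR")) == [0, 2]

    def test_rna_input_normalized(self):
        assert scan_motif("ggUGUAgg", MotifSpec("UGUA")) == [2]

    def test_invalid_pattern(self):
        with pytest.raises(ValueError):
            MotifSpec("AXTAAA")

    def test_matches_brute_force_iupac_expansion(self):
        rng = np.random.default_rng(21)
        spec = MotifSpec("WGYA")
        expansions = {
            "".join(bases)
            for bases in itertools.product(*(IUPAC[c] for c in "WGYA"))
        }
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(4, 200))))
            brute = [i for i in range(len(seq) - 3) if seq[i : i + 4] in expansions]
            assert scan_motif(seq, spec) == brute


class TestWindowFrequency:
    def test_raw_fraction(self):
        # UGUA planted at offset 20 in 2 of 4 sequences; no smoothing
        base = "G" * 50
        seqs = [base[:20] + "TGTA" + base[24:], base[:20] + "TGTA" + base[24:],
                base, base]
        counts = window_match_counts(seqs, MotifSpec("UGUA"))
        freq = window_frequency(seqs, MotifSpec("UGUA"), smooth=1)
        assert counts.max() == 2
        assert freq.max() == pytest.approx(0.5)

    def test_plateau_width_equals_window(self):
        seqs = ["G" * 30 + "TGTA" + "G" * 30] * 5
        counts = window_match_counts(seqs, MotifSpec("UGUA"), window=10)
        assert int((counts == 5).sum()) == 10

    def test_no_matches_all_zero(self):
        assert window_frequency(["G" * 40] * 3, MotifSpec("UGUA")).sum() == 0

    def test_window_defaults_by_motif_length(self):
        assert MotifSpec("UGUA").default_window == 10
        assert MotifSpec("AWUAAA").default_window == 20


class TestHypergeomProfile:
    def test_equal_proportions(self):
        p = positional_hypergeom(np.array([5]), 10, np.array([5]), 10)
        assert p[0] == pytest.approx(1.0)

    def test_known_value(self):
        p = positional_hypergeom(np.array([8]), 10, np.array([2]), 10)
        assert p[0] == pytest.approx(4252 / 184756, rel=1e-9)

    def test_empty_negative_set_missing(self):
        assert np.isnan(positional_hypergeom(np.array([1]), 4, np.array([0]), 0)[0])

    def test_label_swap_preserves_p(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            n1, n2 = int(rng.integers(2, 30)), int(rng.integers(2, 30))
            k1, k2 = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n2 + 1))
            p1 = positional_hypergeom(np.array([k1]), n1, np.array([k2]), n2)[0]
            p2 = positional_hypergeom(np.array([k2]), n2, np.array([k1]), n1)[0]
            assert p1 == pytest.approx(p2, rel=1e-12)


class TestGcAndSmoothing:
    def test_all_gc(self):
        assert np.allclose(gc_profile(["GGGG", "CCCC"], smooth=1), 1.0)

    def test_contrasting_sets_differ_by_one(self):
        gc = gc_profile(["GCGC"], smooth=1)
        at = gc_profile(["ATAT"], smooth=1)
        assert np.allclose(gc - at, 1.0)

    def test_ambiguous_bases_excluded(self):
        prof = gc_profile(["GN", "AN"], smooth=1)
        assert prof[0] == pytest.approx(0.5)
        assert np.isnan(prof[1])

    def test_running_mean_preserves_full_window_mean(self):
        rng = np.random.default_rng(6)
        v = rng.uniform(size=50)
        sm = running_mean(v, 5)
        # interior values are exact 5-point means
        assert sm[10] == pytest.approx(v[8:13].mean())
        # edges shrink instead of padding
        assert sm[0] == pytest.approx(v[0:3].mean())

    def test_even_window_biased_left(self):
        v = np.arange(20.0)
        sm = running_mean(v, 10)
        assert sm[10] == pytest.approx(v[5:15].mean())


class TestDistanceDistribution:
    def _genome_with(self, linker, n=1, spacer="G"):
        # upstream layout: ... TGTA [linker] AATAAA [12 nt] PAS
        left = spacer * (150 - linker - 4 - 6 - 12)
        seq = left + "TGTA" + spacer * linker + "AATAAA" + spacer * 12
        pas = len(seq)
        seq = seq + spacer * 20
        return {"c": seq}, [PasReferenceSite("c", pas, "+")] * n

    def test_linker_definition(self):
        # UGUA at [10,14), AATAAA at [64,70): linker 50
        seq = "G" * 10 + "TGTA" + "G" * 50 + "AATAAA" + "G" * 30
        genome = {"c": seq}
        sites = [PasReferenceSite("c", 90, "+")]
        d = motif_distance_distribution(sites, genome, search_radius=100)
        assert list(d) == [50]

    def test_no_ugua_site_skipped(self):
        genome = {"c": "G" * 60 + "AATAAA" + "G" * 40}
        sites = [PasReferenceSite("c", 80, "+")]
        assert motif_distance_distribution(sites, genome).size == 0

    def test_planted_linker_gives_step_cdf(self):
        genome, sites = self._genome_with(linker=120, n=10)
        d = motif_distance_distribution(sites, genome)
        assert np.all(d == 120)

    def test_binding_requirement_filters_sites(self):
        genome, sites = self._genome_with(linker=50)
        pas = sites[0].position
        near = [PeakRecord(GenomicInterval("c", pas - 60, pas - 20, "+"), "R", "r1")]
        far = [PeakRecord(GenomicInterval("c", 2, 5, "+"), "R", "r1")]
        assert motif_distance_distribution(sites, genome, near).size == 1
        assert motif_distance_distribution(sites, genome, far).size == 0

    def test_minus_strand_equivalent(self):
        genome, sites = self._genome_with(linker=70)
        seq = genome["c"]
        # mirror the construction onto the minus strand
        from apamaps.core import reverse_complement
        rc_genome = {"c": reverse_complement(seq)}
        rc_pos = len(seq) - 1 - sites[0].position
        rc_sites = [PasReferenceSite("c", rc_pos, "-")]
        d_plus = motif_distance_distribution(sites, genome)
        d_minus = motif_distance_distribution(rc_sites, rc_genome)
        assert list(d_plus) == list(d_minus) == [70]


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.text(alphabet="ACGTU", max_size=150))
def test_scan_motif_matches_naive_substring_scan(seq):
    """Exact-pattern scanning agrees with a naive substring walk."""
    spec = MotifSpec("UGUA")
    norm = seq.upper().replace("U", "T")
    naive = [i for i in range(max(0, len(norm) - 3)) if norm[i : i + 4] == "TGTA"]
    assert scan_motif(seq, spec) == naive


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=60),
       st.integers(min_value=1, max_value=12))
def test_running_mean_stays_within_data_range(values, k):
    v = np.array(values)
    sm = running_mean(v, k)
    assert sm.size == v.size
    assert np.all(sm >= v.min() - 1e-12) and np.all(sm <= v.max() + 1e-12)
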