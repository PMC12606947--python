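"""The synthetic cohort: determinism, planted geometry, conservation, and
label consistency."""

from __future__ import annotations

import numpy as np
import pytest

from apamaps.apa import LENGTHENED, NON_CHANGING, SHORTENED
from apamaps.core import fetch_sequence, to_offset
from apamaps.motifs import MotifSpec, scan_motif
from apamaps.simulate import (
    REGULATOR_RBP,
    SimConfig,
    simulate_clip_peaks,
    simulate_dms,
    simulate_expression_and_dpdui,
    simulate_genome,
    simulate_three_prime_reads,
)

SMALL = dict(n_genes=30, seed=7)


class TestConfigValidation:
    def test_bad_fractions(self):
        with pytest.raises(ValueError):
            SimConfig(fraction_lengthened=0.7, fraction_shortened=0.7)
        with pytest.raises(ValueError):
            SimConfig(shift_magnitude=0.0)
        with pytest.raises(ValueError):
            SimConfig(pas_per_exon=1)

    def test_exon_too_short_for_elements(self):
        with pytest.raises(ValueError, match="too"):
            SimConfig(exon_length=520)
        with pytest.raises(ValueError, match="too short"):
            SimConfig(exon_length=900, linker_regulated=400)


class TestGenome:
    def test_deterministic_under_seed(self):
        g1, e1, r1, t1 = simulate_genome(SimConfig(**SMALL))
        g2, e2, r2, t2 = simulate_genome(SimConfig(**SMALL))
        assert g1 == g2 and e1 == e2 and r1 == r2
        assert t1.labels == t2.labels and t1.decoy_positions == t2.decoy_positions

    def test_pas_order_and_reference(self):
        g, exons, reference, truth = simulate_genome(SimConfig(**SMALL))
        ref_set = {(s.chrom, s.position, s.strand) for s in reference}
        for exon in exons:
            pas = truth.pas_positions[exon.gene_id]
            strand = exon.interval.strand
            offs = [to_offset(exon.interval.five_prime, strand, p) for p in pas]
            assert offs == sorted(offs) and len(set(offs)) == len(offs)
            for p in pas:
                assert (exon.interval.chrom, p, strand) in ref_set
        assert len(reference) == len(exons) * 2

    def test_planted_hexamer_and_linker_geometry(self):
        g, exons, _, truth = simulate_genome(SimConfig(**SMALL))
        for exon in exons:
            gene = exon.gene_id
            strand = exon.interval.strand
            for j, pas in enumerate(truth.pas_positions[gene]):
                gap = truth.hexamer_gaps[gene][j]
                linker = truth.linkers[gene][j]
                assert 10 <= gap <= 20
                # fetch hexamer and UGUA at their planted transcript offsets
                anchor = to_offset(exon.interval.five_prime, strand, pas)
                hex_start = anchor - gap - 6
                seq = fetch_sequence(g, exon.interval)
                assert seq[hex_start : hex_start + 6] in ("AATAAA", "ATTAAA")
                ugua_start = hex_start - linker - 4
                assert seq[ugua_start : ugua_start + 4] == "TGTA"

    def test_regulated_distal_linker_differs(self):
        cfg = SimConfig(**SMALL)
        _, _, _, truth = simulate_genome(cfg)
        for gene, label in truth.labels.items():
            want = cfg.linker_regulated if label == LENGTHENED else cfg.linker_background
            assert truth.linkers[gene][-1] == want
            assert truth.linkers[gene][0] == cfg.linker_background

    def test_no_a_runs_without_decoys(self):
        g, _, _, truth = simulate_genome(SimConfig(n_genes=30, seed=7, decoy_fraction=0.0))
        assert truth.decoy_positions == {}
        assert "A" * 7 not in g["chrS"] and "T" * 7 not in g["chrS"]

    def test_decoys_have_a_runs(self):
        g, exons, _, truth = simulate_genome(SimConfig(n_genes=30, seed=7,
                                                       decoy_fraction=1.0))
        assert len(truth.decoy_positions) == 30
        for exon in exons:
            decoy = truth.decoy_positions[exon.gene_id]
            seq = fetch_sequence(g, exon.interval)
            off = to_offset(exon.interval.five_prime, exon.interval.strand, decoy)
            assert seq[off + 1 : off + 9] == "A" * 8


class TestReads:
    def test_deterministic(self):
        cfg = SimConfig(**SMALL)
        _, _, _, truth = simulate_genome(cfg)
        t1 = simulate_three_prime_reads(cfg, truth)
        t2 = simulate_three_prime_reads(cfg, truth)
        assert [t.data for t in t1] == [t.data for t in t2]

    def test_zero_depth_gives_empty_tracks(self):
        cfg = SimConfig(n_genes=10, seed=7, reads_per_exon_mean=0.0, decoy_fraction=0.0)
        _, _, _, truth = simulate_genome(cfg)
        for track in simulate_three_prime_reads(cfg, truth):
            assert track.total() == 0

    def test_reads_confined_to_jitter_window(self):
        cfg = SimConfig(n_genes=10, seed=7, decoy_fraction=0.0)
        _, exons, _, truth = simulate_genome(cfg)
        allowed = set()
        for gene, pas_list in truth.pas_positions.items():
            for pas in pas_list:
                allowed.update(range(pas - 5, pas + 6))
        for track in simulate_three_prime_reads(cfg, truth):
            for (_, _), counts in track.data.items():
                assert set(counts) <= allowed

    def test_usage_shift_within_three_standard_errors(self):
        cfg = SimConfig(n_genes=60, seed=7, fraction_lengthened=0.5,
                        fraction_shortened=0.0, decoy_fraction=0.0)
        _, exons, _, truth = simulate_genome(cfg)
        tracks = simulate_three_prime_reads(cfg, truth)
        ctl = [t for t in tracks if t.sample_id.startswith("control")]
        kd = [t for t in tracks if t.sample_id.startswith("kd")]

        def distal_usage(tracks_, gene):
            pas = truth.pas_positions[gene]
            strand = truth.exon_of(gene).interval.strand
            tot = np.zeros(len(pas))
            for t in tracks_:
                counts = t.data.get(("chrS", strand), {})
                for j, p in enumerate(pas):
                    tot[j] += sum(counts.get(p + d, 0) for d in range(-5, 6))
            return tot[-1] / tot.sum()

        deltas = [
            distal_usage(ctl, g) - distal_usage(kd, g)
            for g, lab in truth.labels.items() if lab == LENGTHENED
        ]
        mean_shift = float(np.mean(deltas))
        n_reads = cfg.reads_per_exon_mean * cfg.n_replicates * 4
        se = np.sqrt(0.25 / n_reads) * np.sqrt(2) / np.sqrt(len(deltas))
        assert abs(mean_shift - cfg.shift_magnitude) < 3 * se + 0.01


class TestPeaksDmsExpression:
    def test_peaks_deterministic_and_centered(self):
        cfg = SimConfig(n_genes=40, seed=7, fraction_lengthened=0.5,
                        fraction_shortened=0.0, clip_enrichment_sd=0.0,
                        clip_background_per_utr=0.0, unexpressed_fraction=0.0)
        _, _, _, truth = simulate_genome(cfg)
        p1 = simulate_clip_peaks(cfg, truth)
        p2 = simulate_clip_peaks(cfg, truth)
        assert p1 == p2
        reg = [p for p in p1 if p.rbp_id == REGULATOR_RBP and p.confidence == "any"]
        assert reg  # sd 0: every regulator peak centered at the planted offset
        for peak in reg:
            gene = None
            for g, lab in truth.labels.items():
                if lab != LENGTHENED:
                    continue
                dpas = truth.pas_positions[g][-1]
                strand = truth.exon_of(g).interval.strand
                center = peak.interval.start + cfg.clip_peak_width // 2
                if to_offset(dpas, strand, center) == cfg.clip_enrichment_center \
                        and peak.interval.strand == strand:
                    gene = g
                    break
            assert gene is not None

    def test_high_confidence_subset_reproducible(self):
        cfg = SimConfig(n_genes=40, seed=7, fraction_lengthened=0.5,
                        fraction_shortened=0.0, clip_enrichment_sd=2.0,
                        clip_background_per_utr=0.0)
        _, _, _, truth = simulate_genome(cfg)
        peaks = simulate_clip_peaks(cfg, truth)
        high = [p for p in peaks if p.confidence == "high"]
        assert high and all(p.rbp_id == REGULATOR_RBP for p in high)

    def test_dms_rates_bounded_and_structured_zero(self):
        cfg = SimConfig(n_genes=20, seed=7, fraction_lengthened=0.5,
                        fraction_shortened=0.0, dms_structured_rate=0.0)
        genome, _, _, truth = simulate_genome(cfg)
        track = simulate_dms(cfg, truth, genome)
        assert track.data
        for (chrom, strand, pos), (base, cov, rate) in track.data.items():
            assert 0.0 <= rate <= 1.0 and base in "AC"
        # structured motif A positions have rate exactly 0
        structured_genes = [g for g, s in truth.structured.items() if s]
        assert structured_genes
        hexamer = MotifSpec("AWTAAA")
        for gene in structured_genes:
            exon = truth.exon_of(gene)
            strand = exon.interval.strand
            dpas = truth.pas_positions[gene][-1]
            gap = truth.hexamer_gaps[gene][-1]
            for k in range(6):
                off = -(gap + 6) + k  # hexamer occupies offsets [-gap-6, -gap)
                gpos = dpas + off if strand == "+" else dpas - off
                entry = track.get("chrS", strand, gpos)
                if entry and entry[0] == "A":
                    assert entry[2] == 0.0

    def test_expression_and_dpdui(self):
        cfg = SimConfig(n_genes=60, seed=7, dpdui_noise_sd=0.0)
        _, _, _, truth = simulate_genome(cfg)
        expr, dpdui = simulate_expression_and_dpdui(cfg, truth)
        assert len(expr.tpm) == 60
        # noise 0: dPDUI equals the planted control-minus-KD shift exactly
        for row in dpdui.itertuples(index=False):
            want = truth.usage_control[row.gene_id][-1] - truth.usage_kd[row.gene_id][-1]
            assert row.dpdui == pytest.approx(want)
            if truth.labels[row.gene_id] != NON_CHANGING:
                assert row.adjusted_p < 0.05
        # non-changing genes sit at zero shift
        nc = dpdui[[truth.labels[g] == NON_CHANGING for g in dpdui["gene_id"]]]
        assert np.allclose(nc["dpdui"], 0.0)
        # unexpressed transcripts are not quantified
        n_expressed = sum(truth.expressed.values())
        assert len(dpdui) == n_expressed
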