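"""Pipeline orchestration: simulate -> call-pas -> call-apa -> binding-atlas
-> rna-map -> motif-map -> dms, with a YAML config and a JSON report.

Every stage reads its inputs from, and writes its outputs to, a shared run
directory, so stages can be re-run individually from the CLI. All stage
outputs are pure functions of config + seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate, apa, atlas, cluster, io, maps, motifs, structure
from .core import GenomicInterval, PasReferenceSite, fetch_sequence
from .motifs import HEXAMER_PATTERN, UGUA_PATTERN, MotifSpec
from .simulate import (
    BACKGROUND_RBP,
    REGULATOR_RBP,
    SimConfig,
    simulate_clip_peaks,
    simulate_dms,
    simulate_expression_and_dpdui,
    simulate_genome,
    simulate_three_prime_reads,
)
from .stats import neg_log10


@dataclass
class CallPasParams:
    min_per_position: int = 10
    min_total: int = 20
    reference_slack: int = 0
    # the hexamer sits 10-20 nt upstream of cleavage; clusters narrower than
    # that geometry need an upstream flank for the hexamer requirement
    hexamer_flank_upstream: int = 30
    keep_filtered: bool = True


@dataclass
class CallApaParams:
    delta_thresh: float = 0.10
    n_support: int = 2
    opposite_tolerance: float = 0.0
    nonchange_min_reads: int = 10
    nonchange_max_delta: float = 0.05
    dpdui_change_thresh: float = 0.20
    dpdui_null_thresh: float = 0.05
    alpha: float = 0.05


@dataclass
class AtlasParams:
    min_median_tpm: float = 1.0
    pas_min_reads: int = 100
    pas_window: int = 500
    extension: int = 500


@dataclass
class RnaMapParams:
    window: int = 300
    n_boot: int = 100
    percentiles: tuple[float, float] = (25.0, 75.0)


@dataclass
class MotifMapParams:
    flank: int = 300
    search_radius: int = 150
    binding_radius: int = 100
    smooth_motif: int = 5
    smooth_gc: int = 10


@dataclass
class DmsParams:
    upstream_window: int = 100
    min_cov: int = 100


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: SimConfig = field(default_factory=SimConfig)
    call_pas: CallPasParams = field(default_factory=CallPasParams)
    call_apa: CallApaParams = field(default_factory=CallApaParams)
    atlas: AtlasParams = field(default_factory=AtlasParams)
    rna_map: RnaMapParams = field(default_factory=RnaMapParams)
    motif_map: MotifMapParams = field(default_factory=MotifMapParams)
    dms: DmsParams = field(default_factory=DmsParams)

    def __post_init__(self) -> None:
        self.simulate.seed = self.seed


_SECTIONS = {
    "simulate": SimConfig,
    "call_pas": CallPasParams,
    "call_apa": CallApaParams,
    "atlas": AtlasParams,
    "rna_map": RnaMapParams,
    "motif_map": MotifMapParams,
    "dms": DmsParams,
}


def _build_section(cls, data: dict, section: str):
    valid = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in valid:
            raise ValueError(f"config section '{section}': unknown key '{key}'")
        ftype = valid[key].type
        if ftype in ("int", int) and not isinstance(value, int):
            raise TypeError(f"config {section}.{key}: expected int, got {value!r}")
        if ftype in ("float", float) and not isinstance(value, (int, float)):
            raise TypeError(f"config {section}.{key}: expected number, got {value!r}")
        if ftype in ("bool", bool) and not isinstance(value, bool):
            raise TypeError(f"config {section}.{key}: expected bool, got {value!r}")
        kwargs[key] = tuple(value) if isinstance(value, list) else value
    return cls(**kwargs)


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML run configuration (schema errors raise
    before any compute)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    kwargs = {}
    for key, value in raw.items():
        if key == "seed":
            if not isinstance(value, int):
                raise TypeError(f"config seed: expected int, got {value!r}")
            kwargs["seed"] = value
        elif key in _SECTIONS:
            if not isinstance(value, dict):
                raise TypeError(f"config section '{key}' must be a mapping")
            kwargs[key] = _build_section(_SECTIONS[key], value, key)
        else:
            raise ValueError(f"unknown config key '{key}'")
    return PipelineConfig(**kwargs)


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}': missing input {path} (produced by stage '{produced_by}')"
        )
    return path


def _coverage_paths(outdir: Path, sample: str) -> tuple[Path, Path]:
    cov = outdir / "coverage"
    return cov / f"{sample}.plus.bedgraph", cov / f"{sample}.minus.bedgraph"


# ---------------------------------------------------------------------------
# stages

def stage_simulate(config: PipelineConfig, outdir: Path) -> None:
    """Generate the synthetic cohort and write every pipeline input."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulate
    genome, exons, reference, truth = simulate_genome(sim)
    io.write_fasta(genome, outdir / "genome.fa")
    io.write_exon_table(exons, outdir / "terminal_exons.tsv")
    io.write_pas_bed(reference, outdir / "reference_pas.bed")
    (outdir / "coverage").mkdir(exist_ok=True)
    for track in simulate_three_prime_reads(sim, truth):
        io.write_coverage(track, *_coverage_paths(outdir, track.sample_id))
    io.write_peaks_bed(simulate_clip_peaks(sim, truth), outdir / "clip_peaks.bed")
    io.write_dms_table(simulate_dms(sim, truth, genome), outdir / "dms.tsv")
    expr, dpdui = simulate_expression_and_dpdui(sim, truth)
    io.write_expression_table(expr, outdir / "expression.tsv")
    io.write_dpdui_table(dpdui, outdir / "dpdui.tsv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth.to_jsonable(), fh, indent=1, sort_keys=True)


def _read_tracks(config: PipelineConfig, outdir: Path, stage: str):
    tracks = []
    for sample in config.simulate.sample_ids():
        plus, minus = _coverage_paths(outdir, sample)
        _require(plus, stage, "simulate")
        _require(minus, stage, "simulate")
        tracks.append(io.read_coverage(sample, plus, minus))
    return tracks


def stage_call_pas(config: PipelineConfig, outdir: Path) -> None:
    """Call 3'-end clusters, apply filters, and compute relative usage."""
    outdir = Path(outdir)
    stage = "call-pas"
    genome = io.read_fasta(_require(outdir / "genome.fa", stage, "simulate"))
    exons = io.read_exon_table(_require(outdir / "terminal_exons.tsv", stage, "simulate"))
    reference = io.read_pas_bed(_require(outdir / "reference_pas.bed", stage, "simulate"))
    tracks = _read_tracks(config, outdir, stage)
    p = config.call_pas

    combined = cluster.combine_tracks(tracks)
    clusters = cluster.call_clusters(
        combined, p.min_per_position, p.min_total, keep_filtered=p.keep_filtered
    )
    for c in clusters:
        cluster.assign_pas(c, combined)
    funnel = cluster.apply_filters(
        clusters, genome, reference,
        reference_slack=p.reference_slack,
        hexamer_flank_upstream=p.hexamer_flank_upstream,
    )
    passed = [c for c in clusters if c.passed]
    assigned = cluster.assign_terminal_exon(passed, exons)
    funnel.loc[len(funnel)] = ["terminal_exon", len(assigned)]
    cluster.name_clusters(assigned)
    cluster.attach_sample_counts(assigned, tracks)
    usage, counts = cluster.compute_relative_usage(assigned, config.simulate.sample_ids())

    # cluster BED: score = pooled reads, name = exon:index, thick = PAS
    with open(outdir / "clusters.bed", "w") as fh:
        for c in sorted(assigned, key=lambda c: (c.interval.chrom, c.interval.start)):
            iv = c.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{c.cluster_id}\t{c.total}\t"
                f"{iv.strand}\t{c.pas_position}\t{c.pas_position + 1}\n"
            )
    # flagged clusters, for the filter funnel and decoy diagnostics
    flagged_rows = [
        [c.interval.chrom, c.interval.start, c.interval.end, c.interval.strand,
         c.pas_position, c.total, ",".join(sorted(c.flags)) or "."]
        for c in clusters
    ]
    pd.DataFrame(
        flagged_rows,
        columns=["chrom", "start", "end", "strand", "pas", "total", "flags"],
    ).to_csv(outdir / "cluster_flags.tsv", sep="\t", index=False)
    funnel.to_csv(outdir / "funnel.tsv", sep="\t", index=False)
    usage.reset_index().to_csv(outdir / "usage.tsv", sep="\t", index=False)
    counts.reset_index().to_csv(outdir / "counts.tsv", sep="\t", index=False)
    # PAS positions per cluster, for event anchoring downstream
    pd.DataFrame(
        [[c.terminal_exon_id, c.cluster_id, c.interval.chrom, c.interval.strand,
          c.pas_position] for c in assigned],
        columns=["terminal_exon_id", "cluster_id", "chrom", "strand", "pas"],
    ).to_csv(outdir / "cluster_pas.tsv", sep="\t", index=False)


def _read_usage(outdir: Path, name: str, stage: str) -> pd.DataFrame:
    path = _require(outdir / name, stage, "call-pas")
    df = pd.read_csv(path, sep="\t")
    return df.set_index(["terminal_exon_id", "cluster_id"])


def stage_call_apa(config: PipelineConfig, outdir: Path) -> dict:
    """Call APA changes per compartment and classify the dPDUI table."""
    outdir = Path(outdir)
    stage = "call-apa"
    usage = _read_usage(outdir, "usage.tsv", stage)
    counts = _read_usage(outdir, "counts.tsv", stage)
    p = config.call_apa

    all_calls = []
    nonchanging = {}
    directions = {}
    for fraction in ("nuclear", "cytoplasmic"):
        pairing = config.simulate.pairing(fraction)
        calls = apa.call_pas_changes(
            usage, pairing, p.delta_thresh, p.n_support, p.opposite_tolerance,
            compartment=fraction,
        )
        all_calls.append(calls)
        nonchanging[fraction] = apa.call_nonchanging(
            usage, counts, pairing, p.nonchange_min_reads, p.nonchange_max_delta
        )
        directions[fraction] = apa.exon_direction(calls)

    comparison = apa.compare_compartments(
        all_calls[0], all_calls[1], nonchanging["nuclear"], nonchanging["cytoplasmic"]
    )
    universe = sorted({e for e, _ in usage.index})
    fisher_p, jaccard, same_dir = apa.overlap_stats(
        directions["nuclear"], directions["cytoplasmic"], universe,
        directions["nuclear"], directions["cytoplasmic"],
    )

    rows = []
    for calls in all_calls:
        for c in calls:
            rows.append([c.terminal_exon_id, c.cluster_id, c.compartment, c.status]
                        + list(c.deltas))
    n_rep = config.simulate.n_replicates
    pd.DataFrame(
        rows,
        columns=["terminal_exon_id", "cluster_id", "compartment", "status"]
        + [f"delta_rep{i + 1}" for i in range(n_rep)],
    ).to_csv(outdir / "apa_calls.tsv", sep="\t", index=False)
    for fraction, exon_ids in nonchanging.items():
        (outdir / f"nonchanging_{fraction}.txt").write_text(
            "".join(f"{g}\n" for g in exon_ids)
        )

    dpdui = io.read_dpdui_table(_require(outdir / "dpdui.tsv", stage, "simulate"))
    events = apa.classify_dpdui(
        dpdui, p.dpdui_change_thresh, p.dpdui_null_thresh, p.alpha
    )
    io.write_dpdui_table(events, outdir / "events.tsv")

    summary = {
        "compartments": {k: len(v) for k, v in comparison.items()},
        "compartment_overlap": {
            "fisher_p": fisher_p, "jaccard": jaccard, "same_direction_fraction": same_dir,
        },
        "event_counts": events["label"].value_counts().to_dict(),
        "n_changing": {f: len(d) for f, d in directions.items()},
    }
    with open(outdir / "compartments.json", "w") as fh:
        json.dump({"lists": comparison, "summary": summary}, fh, indent=1, sort_keys=True)
    return summary


def stage_binding_atlas(config: PipelineConfig, outdir: Path) -> dict:
    """Rank RBPs by 3'UTR binding and profile PAS-proximal occupancy."""
    outdir = Path(outdir)
    stage = "binding-atlas"
    expr = io.read_expression_table(_require(outdir / "expression.tsv", stage, "simulate"))
    peaks = io.read_peaks_bed(_require(outdir / "clip_peaks.bed", stage, "simulate"))
    exons = io.read_exon_table(_require(outdir / "terminal_exons.tsv", stage, "simulate"))
    reference = io.read_pas_bed(_require(outdir / "reference_pas.bed", stage, "simulate"))
    tracks = _read_tracks(config, outdir, stage)
    p = config.atlas

    utrs = atlas.select_expressed(expr, p.min_median_tpm)
    rbps = sorted({pk.rbp_id for pk in peaks})
    any_peaks = {r: [pk for pk in peaks if pk.rbp_id == r and pk.confidence == "any"]
                 for r in rbps}
    high_peaks = {r: [pk for pk in peaks if pk.rbp_id == r and pk.confidence == "high"]
                  for r in rbps}

    bound = {r: atlas.utr_bound_fraction(any_peaks[r], utrs) for r in rbps}
    pd.DataFrame(sorted(bound.items(), key=lambda kv: -kv[1]),
                 columns=["rbp", "bound_utr_fraction"]).to_csv(
        outdir / "atlas_bound_fraction.tsv", sep="\t", index=False)

    # region annotation from the exon table: 3'UTR, CDS part of the terminal
    # exon, and the downstream extension
    extended = annotate.extend_gene_ends([ex.interval for ex in exons], p.extension)
    regions = {
        "three_prime_utr": list(utrs.values()),
        "cds": [
            GenomicInterval(ex.interval.chrom,
                            ex.interval.start if ex.interval.strand == "+" else ex.cds_end + 1,
                            ex.cds_end if ex.interval.strand == "+" else ex.interval.end,
                            ex.interval.strand)
            for ex in exons if ex.cds_end is not None
        ],
        "downstream": [g.extension_region for g in extended if g.extension_region],
    }
    comp_rows = []
    for r in rbps:
        comp = atlas.peak_region_composition(high_peaks[r], regions)
        comp_rows.append([r] + [comp.get(k, 0.0) for k in
                                ("three_prime_utr", "cds", "downstream", "unassigned")])
    pd.DataFrame(comp_rows, columns=["rbp", "three_prime_utr", "cds", "downstream",
                                     "unassigned"]).to_csv(
        outdir / "atlas_composition.tsv", sep="\t", index=False)

    combined = cluster.combine_tracks(tracks)
    expressed_pas = []
    for site in reference:
        counts = combined.get((site.chrom, site.strand), {})
        pooled = sum(counts.get(site.position + d, 0) for d in range(-5, 6))
        if pooled >= p.pas_min_reads:
            expressed_pas.append((site.chrom, site.position, site.strand))
    profiles = {}
    for r in rbps:
        offs, frac = atlas.pas_proximal_frequency(any_peaks[r], expressed_pas, p.pas_window)
        profiles[r] = frac
    prof = pd.DataFrame(profiles)
    prof.insert(0, "offset", offs if expressed_pas else np.arange(-p.pas_window, p.pas_window + 1))
    prof.to_csv(outdir / "atlas_profile.tsv", sep="\t", index=False)

    jac = atlas.pairwise_peak_jaccard(any_peaks)
    jac.to_csv(outdir / "atlas_jaccard.tsv", sep="\t")

    n_peaks, frac_overlap = annotate.flag_overlap_peaks(peaks, extended)
    summary = {
        "bound_utr_fraction": bound,
        "n_expressed_utrs": len(utrs),
        "n_expressed_pas": len(expressed_pas),
        "peaks_in_overlap_regions": {"count": n_peaks, "fraction": frac_overlap},
    }
    with open(outdir / "atlas_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def _load_events(outdir: Path, stage: str) -> pd.DataFrame:
    return io.read_dpdui_table(_require(outdir / "events.tsv", stage, "call-apa"))


def stage_rna_map(config: PipelineConfig, outdir: Path) -> dict:
    """Positional peak-occupancy maps around regulated PAS with Fisher tests."""
    outdir = Path(outdir)
    stage = "rna-map"
    events = _load_events(outdir, stage)
    peaks = io.read_peaks_bed(_require(outdir / "clip_peaks.bed", stage, "simulate"))
    p = config.rna_map
    reg = events[events["label"] == apa.LENGTHENED]
    ctl = events[events["label"] == apa.NON_CHANGING]
    reg_peaks = [pk for pk in peaks if pk.rbp_id == REGULATOR_RBP and pk.confidence == "any"]

    summary = {}
    for anchor in ("pPAS", "dPAS"):
        m_reg = maps.event_window_matrix(reg, reg_peaks, anchor, p.window)
        m_ctl = maps.event_window_matrix(ctl, reg_peaks, anchor, p.window)
        prof_reg = maps.fraction_with_bootstrap(
            m_reg, anchor, p.n_boot, tuple(p.percentiles), seed=config.seed
        )
        prof_ctl = maps.fraction_with_bootstrap(
            m_ctl, anchor, p.n_boot, tuple(p.percentiles), seed=config.seed + 1
        )
        pvals = maps.positional_fisher(m_reg, m_ctl)
        df = prof_reg.to_frame().rename(columns={
            "fraction": "fraction_regulated", "band_low": "band_low_regulated",
            "band_high": "band_high_regulated"})
        ctl_df = prof_ctl.to_frame().rename(columns={
            "fraction": "fraction_nonchanging", "band_low": "band_low_nonchanging",
            "band_high": "band_high_nonchanging"})
        df = df.merge(ctl_df, on="offset")
        df["p"] = pvals
        df.to_csv(outdir / f"rnamap_{anchor.lower()}.tsv", sep="\t", index=False)
        if np.all(np.isnan(pvals)):
            summary[anchor] = {"peak_offset": None, "min_p": None}
        else:
            j = int(np.nanargmin(pvals))
            summary[anchor] = {
                "peak_offset": int(prof_reg.offsets[j]),
                "min_p": float(pvals[j]),
                "neg_log10_p": neg_log10(pvals[j]),
                "n_regulated": int(m_reg.shape[0]),
                "n_nonchanging": int(m_ctl.shape[0]),
            }
    with open(outdir / "rnamap_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def _anchor_sequences(genome, events: pd.DataFrame, anchor_col: str, flank: int) -> list[str]:
    out = []
    chrom_len = {c: len(s) for c, s in genome.items()}
    for row in events.itertuples(index=False):
        pos = int(getattr(row, anchor_col))
        lo, hi = pos - flank, pos + flank + 1
        if lo < 0 or hi > chrom_len[row.chrom]:
            continue
        iv = GenomicInterval(row.chrom, lo, hi, row.strand)
        out.append(fetch_sequence(genome, iv))
    return out


def stage_motif_map(config: PipelineConfig, outdir: Path) -> dict:
    """Motif frequency and GC maps around the dPAS, plus UGUA-hexamer spacing."""
    outdir = Path(outdir)
    stage = "motif-map"
    genome = io.read_fasta(_require(outdir / "genome.fa", stage, "simulate"))
    events = _load_events(outdir, stage)
    peaks = io.read_peaks_bed(_require(outdir / "clip_peaks.bed", stage, "simulate"))
    p = config.motif_map

    reg = events[events["label"] == apa.LENGTHENED]
    ctl = events[events["label"] == apa.NON_CHANGING]
    seqs_reg = _anchor_sequences(genome, reg, "dpas", p.flank)
    seqs_ctl = _anchor_sequences(genome, ctl, "dpas", p.flank)

    specs = {
        "ugua": MotifSpec(UGUA_PATTERN),
        "ugua_rc": MotifSpec(UGUA_PATTERN, "reverse_complement"),
        "hexamer": MotifSpec(HEXAMER_PATTERN),
        "hexamer_rc": MotifSpec(HEXAMER_PATTERN, "reverse_complement"),
    }
    offsets = np.arange(-p.flank, p.flank + 1)
    for name, spec in specs.items():
        freq_reg = motifs.window_frequency(seqs_reg, spec, smooth=p.smooth_motif)
        freq_ctl = motifs.window_frequency(seqs_ctl, spec, smooth=p.smooth_motif)
        k_reg = motifs.window_match_counts(seqs_reg, spec)
        k_ctl = motifs.window_match_counts(seqs_ctl, spec)
        pvals = motifs.positional_hypergeom(k_reg, len(seqs_reg), k_ctl, len(seqs_ctl))
        pd.DataFrame({
            "offset": offsets,
            "freq_regulated": freq_reg,
            "freq_nonchanging": freq_ctl,
            "p": pvals,
        }).to_csv(outdir / f"motif_{name}.tsv", sep="\t", index=False)

    gc = pd.DataFrame({
        "offset": offsets,
        "gc_regulated": motifs.gc_profile(seqs_reg, p.smooth_gc),
        "gc_nonchanging": motifs.gc_profile(seqs_ctl, p.smooth_gc),
    })
    gc.to_csv(outdir / "motif_gc.tsv", sep="\t", index=False)

    reg_peaks = [pk for pk in peaks if pk.rbp_id == REGULATOR_RBP and pk.confidence == "any"]
    sites_reg = [PasReferenceSite(r.chrom, int(r.dpas), r.strand)
                 for r in reg.itertuples(index=False)]
    sites_ctl = [PasReferenceSite(r.chrom, int(r.dpas), r.strand)
                 for r in ctl.itertuples(index=False)]
    d_reg = motifs.motif_distance_distribution(
        sites_reg, genome, reg_peaks, p.search_radius, p.binding_radius)
    d_ctl = motifs.motif_distance_distribution(
        sites_ctl, genome, None, p.search_radius, p.binding_radius)
    summary = {
        "spacing_regulated_median": float(np.median(d_reg)) if d_reg.size else None,
        "spacing_nonchanging_median": float(np.median(d_ctl)) if d_ctl.size else None,
        "n_regulated_sites": int(d_reg.size),
        "n_nonchanging_sites": int(d_ctl.size),
    }
    pd.DataFrame({"set": ["regulated"] * d_reg.size + ["nonchanging"] * d_ctl.size,
                  "linker": np.concatenate([d_reg, d_ctl]) if (d_reg.size + d_ctl.size)
                  else []}).to_csv(outdir / "motif_spacing.tsv", sep="\t", index=False)
    with open(outdir / "motif_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def stage_dms(config: PipelineConfig, outdir: Path) -> dict:
    """DMS accessibility of PAS-proximal motifs, regulated vs non-changing."""
    outdir = Path(outdir)
    stage = "dms"
    genome = io.read_fasta(_require(outdir / "genome.fa", stage, "simulate"))
    dms_track = io.read_dms_table(_require(outdir / "dms.tsv", stage, "simulate"))
    events = _load_events(outdir, stage)
    p = config.dms

    reg = events[events["label"] == apa.LENGTHENED]
    ctl = events[events["label"] == apa.NON_CHANGING]
    sites = {
        "regulated": [PasReferenceSite(r.chrom, int(r.dpas), r.strand)
                      for r in reg.itertuples(index=False)],
        "nonchanging": [PasReferenceSite(r.chrom, int(r.dpas), r.strand)
                        for r in ctl.itertuples(index=False)],
    }
    summary = {}
    score_rows = []
    for motif_name, pattern in (("hexamer", HEXAMER_PATTERN), ("ugua", UGUA_PATTERN)):
        spec = MotifSpec(pattern)
        scores = {
            group: structure.motif_dms_scores(
                group_sites, spec, dms_track, genome, p.upstream_window, p.min_cov
            )
            for group, group_sites in sites.items()
        }
        for group, vals in scores.items():
            score_rows += [[motif_name, group, v] for v in vals]
        if scores["regulated"].size and scores["nonchanging"].size:
            d, pval = structure.compare_accessibility(
                scores["regulated"], scores["nonchanging"]
            )
            summary[motif_name] = {
                "ks_D": d, "ks_p": pval,
                "n_regulated": int(scores["regulated"].size),
                "n_nonchanging": int(scores["nonchanging"].size),
                "median_regulated": float(np.median(scores["regulated"])),
                "median_nonchanging": float(np.median(scores["nonchanging"])),
            }
        else:
            summary[motif_name] = {"ks_D": None, "ks_p": None}
    pd.DataFrame(score_rows, columns=["motif", "set", "max_A_rate"]).to_csv(
        outdir / "dms_scores.tsv", sep="\t", index=False)
    with open(outdir / "dms_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


# ---------------------------------------------------------------------------
# full run and truth-aware report

def _truth_confusion(config: PipelineConfig, outdir: Path) -> dict:
    with open(outdir / "truth.json") as fh:
        truth = json.load(fh)
    calls = pd.read_csv(outdir / "apa_calls.tsv", sep="\t")
    nuclear = calls[calls["compartment"] == "nuclear"]
    called = {}
    for exon_id, grp in nuclear[nuclear["status"] != "not_called"].groupby("terminal_exon_id"):
        grp = grp.assign(idx=grp["cluster_id"].str.rsplit(":", n=1).str[1].astype(int))
        distal = grp.sort_values("idx").iloc[-1]
        called[exon_id] = (
            apa.LENGTHENED if distal["status"] == "decreased" else apa.SHORTENED
        )
    confusion: dict[str, dict[str, int]] = {}
    quantified = set(calls["terminal_exon_id"])
    for gene, label in truth["labels"].items():
        if gene not in quantified:
            continue
        pred = called.get(gene, "not_called")
        confusion.setdefault(label, {}).setdefault(pred, 0)
        confusion[label][pred] += 1

    # per-PAS sensitivity / false-positive rate against planted shifts
    truth_dir = {}
    for gene, label in truth["labels"].items():
        n_pas = len(truth["pas_positions"][gene])
        if label == apa.LENGTHENED:
            # knockdown shifts toward the proximal site
            dirs = ["increased"] + ["none"] * (n_pas - 2) + ["decreased"]
        elif label == apa.SHORTENED:
            dirs = ["decreased"] + ["none"] * (n_pas - 2) + ["increased"]
        else:
            dirs = ["none"] * n_pas
        for j, d in enumerate(dirs):
            truth_dir[f"{gene}:{j}"] = d
    tp = fn = fp = tn = 0
    for row in nuclear.itertuples(index=False):
        expected = truth_dir.get(row.cluster_id)
        if expected is None:
            continue
        if expected == "none":
            if row.status == "not_called":
                tn += 1
            else:
                fp += 1
        else:
            if row.status == expected:
                tp += 1
            else:
                fn += 1
    sens = tp / (tp + fn) if tp + fn else float("nan")
    fpr = fp / (fp + tn) if fp + tn else float("nan")
    return {
        "confusion": confusion,
        "sensitivity": sens,
        "false_positive_rate": fpr,
        "n_regulated_pas": tp + fn,
        "n_unregulated_pas": fp + tn,
    }


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage and write a machine-readable summary report."""
    outdir = Path(outdir)
    stage_simulate(config, outdir)
    stage_call_pas(config, outdir)
    apa_summary = stage_call_apa(config, outdir)
    atlas_summary = stage_binding_atlas(config, outdir)
    rnamap_summary = stage_rna_map(config, outdir)
    motif_summary = stage_motif_map(config, outdir)
    dms_summary = stage_dms(config, outdir)
    funnel = pd.read_csv(outdir / "funnel.tsv", sep="\t")
    report = {
        "seed": config.seed,
        "funnel": dict(zip(funnel["stage"], funnel["clusters"].astype(int))),
        "apa": apa_summary,
        "atlas": atlas_summary,
        "rna_map": rnamap_summary,
        "motif_map": motif_summary,
        "dms": dms_summary,
        "truth_recovery": _truth_confusion(config, outdir),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
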