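"""DMS accessibility of cleavage/polyadenylation motifs.

DMS modifies unpaired adenosines (and cytosines); a low mutation rate at a
motif's A positions implies the motif is base-paired. For each reference
PAS, motifs in the 100 nt upstream are scored by the maximum mutation rate
over their covered A positions, and regulated versus non-regulated score
distributions are compared with a two-tailed Kolmogorov-Smirnov test.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .core import DmsTrack, GenomicInterval, fetch_sequence, from_offset
from .motifs import MotifSpec, scan_motif
from .stats import ks_two_sample

UPSTREAM_WINDOW = 100
MIN_COVERAGE = 100


def motif_dms_scores(
    pas_sites: Sequence,
    motif: MotifSpec,
    dms: DmsTrack,
    genome: Mapping[str, str],
    upstream_window: int = UPSTREAM_WINDOW,
    min_cov: int = MIN_COVERAGE,
    per_pas_max: bool = False,
) -> np.ndarray:
    """Maximum A-position mutation rate per motif occurrence upstream of PAS.

    Only positions with coverage >= ``min_cov`` count; occurrences with no
    sufficiently covered A are excluded ("sufficient data"). With
    ``per_pas_max`` each PAS contributes a single value, the maximum over
    its occurrences; otherwise occurrences pool across sites.
    """
    scores = []
    for site in pas_sites:
        chrom, pos, strand = site.chrom, site.position, site.strand
        if strand == "+":
            start = max(0, pos - upstream_window)
            if pos <= start:
                continue
            region = GenomicInterval(chrom, start, pos, strand)
        else:
            end = min(len(genome[chrom]), pos + 1 + upstream_window)
            if end <= pos + 1:
                continue
            region = GenomicInterval(chrom, pos + 1, end, strand)
        seq = fetch_sequence(genome, region)
        site_scores = []
        for start_off in scan_motif(seq, motif):
            rates = []
            for k in range(len(motif.pattern)):
                off = start_off + k
                if seq[off] != "A":
                    continue
                # transcript offset within region -> genomic position
                gpos = (region.start + off if strand == "+" else region.end - 1 - off)
                entry = dms.get(chrom, strand, gpos)
                if entry is None:
                    continue
                _, cov, rate = entry
                if cov >= min_cov:
                    rates.append(rate)
            if rates:
                site_scores.append(max(rates))
        if per_pas_max and site_scores:
            scores.append(max(site_scores))
        elif not per_pas_max:
            scores.extend(site_scores)
    return np.array(scores, dtype=float)


def compare_accessibility(
    scores_regulated: np.ndarray, scores_control: np.ndarray
) -> tuple[float, float]:
    """Two-sample two-tailed KS test on motif accessibility scores."""
    return ks_two_sample(scores_regulated, scores_control)
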