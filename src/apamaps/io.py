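"""Readers and writers for the external formats the pipeline touches.

Formats: FASTA (via Biopython), BED6, strand-split bedGraph pairs, and the
tab-delimited exon / expression / DMS / dPDUI tables documented below.
Machine outputs are always 0-based half-open (BED convention).
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    CoverageTrack,
    DmsTrack,
    ExpressionTable,
    GenomicInterval,
    PasReferenceSite,
    PeakRecord,
    TerminalExon,
    normalize_seq,
)


def _parse_error(path, lineno: int, msg: str) -> ValueError:
    return ValueError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    return {rec.id: normalize_seq(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# BED6 and friends

def read_intervals(path, format: str = "bed6"):
    """Read intervals from ``path`` under the named dialect.

    - ``bed6``: chrom, start, end, name, score, strand -> GenomicInterval
    - ``exon_table``: gene_id, chrom, start, end, strand, cds_end ('.' for
      none) -> TerminalExon
    - ``pas_bed``: BED6 of single positions (end = start + 1)
      -> PasReferenceSite
    """
    if format == "bed6":
        return _read_bed6(path)
    if format == "exon_table":
        return read_exon_table(path)
    if format == "pas_bed":
        return read_pas_bed(path)
    raise ValueError(f"unknown format {format!r}")


def _read_bed6(path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise _parse_error(path, lineno, f"expected >= 6 BED fields, got {len(fields)}")
            try:
                iv = GenomicInterval(
                    fields[0], int(fields[1]), int(fields[2]), fields[5], id=fields[3]
                )
            except ValueError as exc:
                raise _parse_error(path, lineno, str(exc)) from exc
            out.append(iv)
    return out


def write_bed6(intervals: Iterable[GenomicInterval], path, scores=None) -> None:
    intervals = list(intervals)
    if scores is None:
        scores = [0] * len(intervals)
    with open(path, "w") as fh:
        for iv, score in zip(intervals, scores):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id or '.'}\t{score}\t{iv.strand}\n")


def read_pas_bed(path) -> list[PasReferenceSite]:
    return [
        PasReferenceSite(iv.chrom, iv.start, iv.strand) for iv in _read_bed6(path)
    ]


def write_pas_bed(sites: Iterable[PasReferenceSite], path) -> None:
    write_bed6(
        [GenomicInterval(s.chrom, s.position, s.position + 1, s.strand, id="pas") for s in sites],
        path,
    )


# peaks round-trip through BED6 with the name column encoding
# "<rbp>|<replicate>|<confidence>" and score holding the peak score.

def write_peaks_bed(peaks: Iterable[PeakRecord], path) -> None:
    peaks = list(peaks)
    write_bed6(
        [
            GenomicInterval(
                p.interval.chrom,
                p.interval.start,
                p.interval.end,
                p.interval.strand,
                id=f"{p.rbp_id}|{p.replicate}|{p.confidence}",
            )
            for p in peaks
        ],
        path,
        scores=[p.score for p in peaks],
    )


def read_peaks_bed(path) -> list[PeakRecord]:
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise _parse_error(path, lineno, "expected 6 BED fields")
            rbp, replicate, confidence = f[3].split("|")
            peaks.append(
                PeakRecord(
                    GenomicInterval(f[0], int(f[1]), int(f[2]), f[5]),
                    rbp_id=rbp,
                    replicate=replicate,
                    confidence=confidence,
                    score=float(f[4]),
                )
            )
    return peaks


# ---------------------------------------------------------------------------
# exon table

EXON_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "cds_end"]


def read_exon_table(path) -> list[TerminalExon]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("gene_id"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise _parse_error(path, lineno, "expected 6 columns")
            try:
                iv = GenomicInterval(f[1], int(f[2]), int(f[3]), f[4], id=f[0])
                cds_end = None if f[5] in (".", "") else int(f[5])
                out.append(TerminalExon(f[0], iv, cds_end))
            except ValueError as exc:
                raise _parse_error(path, lineno, str(exc)) from exc
    return out


def write_exon_table(exons: Iterable[TerminalExon], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(EXON_COLUMNS) + "\n")
        for ex in exons:
            iv = ex.interval
            cds = "." if ex.cds_end is None else str(ex.cds_end)
            fh.write(f"{ex.gene_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t{cds}\n")


# ---------------------------------------------------------------------------
# bedGraph (strand-split pairs)

def read_coverage(sample_id: str, path_plus, path_minus) -> CoverageTrack:
    """Read a strand-split bedGraph pair into per-position 3'-end counts.

    Interval records are expanded per position; overlapping records are
    summed. Values must be non-negative integers.
    """
    track = CoverageTrack(sample_id)
    for strand, path in (("+", path_plus), ("-", path_minus)):
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                f = line.split("\t")
                if len(f) < 4:
                    raise _parse_error(path, lineno, "expected 4 bedGraph fields")
                chrom, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
                if value < 0:
                    raise _parse_error(path, lineno, f"negative value {value}")
                count = int(value)
                if count != value:
                    raise _parse_error(path, lineno, f"non-integer count {value}")
                if count == 0:
                    continue
                for pos in range(start, end):
                    track.add(chrom, strand, pos, count)
    return track


def write_coverage(track: CoverageTrack, path_plus, path_minus) -> None:
    """Write a track as a strand-split bedGraph pair (run-length merged)."""
    for strand, path in (("+", path_plus), ("-", path_minus)):
        with open(path, "w") as fh:
            for (chrom, s), counts in sorted(track.data.items()):
                if s != strand:
                    continue
                run_start = run_val = None
                prev = None
                for pos in sorted(counts):
                    val = counts[pos]
                    if val == 0:
                        continue
                    if run_start is not None and pos == prev + 1 and val == run_val:
                        prev = pos
                        continue
                    if run_start is not None:
                        fh.write(f"{chrom}\t{run_start}\t{prev + 1}\t{run_val}\n")
                    run_start, run_val, prev = pos, val, pos
                if run_start is not None:
                    fh.write(f"{chrom}\t{run_start}\t{prev + 1}\t{run_val}\n")


# ---------------------------------------------------------------------------
# expression table

def read_expression_table(path) -> ExpressionTable:
    """TSV with columns transcript_id, chrom, start, end, strand, tpm_1..tpm_n."""
    df = pd.read_csv(path, sep="\t")
    tpm_cols = [c for c in df.columns if c.startswith("tpm_")]
    table = ExpressionTable()
    for row in df.itertuples(index=False):
        utr = GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand,
                              id=row.transcript_id)
        table.add(row.transcript_id, [getattr(row, c) for c in tpm_cols], utr)
    return table


def write_expression_table(table: ExpressionTable, path) -> None:
    n = max((len(v) for v in table.tpm.values()), default=0)
    cols = ["transcript_id", "chrom", "start", "end", "strand"] + [
        f"tpm_{i + 1}" for i in range(n)
    ]
    rows = []
    for tid, tpms in table.tpm.items():
        utr = table.utr[tid]
        rows.append([tid, utr.chrom, utr.start, utr.end, utr.strand] + list(tpms))
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# DMS track

DMS_COLUMNS = ["chrom", "pos", "strand", "base", "coverage", "rate"]


def read_dms_table(path) -> DmsTrack:
    df = pd.read_csv(path, sep="\t")
    track = DmsTrack()
    for row in df.itertuples(index=False):
        track.set(row.chrom, row.strand, int(row.pos), row.base, int(row.coverage),
                  float(row.rate))
    return track


def write_dms_table(track: DmsTrack, path) -> None:
    rows = [
        [chrom, pos, strand, base, cov, rate]
        for (chrom, strand, pos), (base, cov, rate) in sorted(track.data.items())
    ]
    pd.DataFrame(rows, columns=DMS_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# dPDUI table (DaPars-style)

DPDUI_COLUMNS = ["gene_id", "chrom", "strand", "ppas", "dpas", "dpdui", "adjusted_p"]


def read_dpdui_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_dpdui_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
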