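"""Readers and writers for the on-disk formats the pipeline touches.

Supported dialects:

* per-CpG calls as bedGraph-with-counts
  (``chrom  start  end  %meth  n_meth  n_unmeth``, 0-based half-open) or as a
  bismark-style cytosine report
  (``chrom  pos(1-based)  strand  n_meth  n_unmeth  context``);
* BED3/BED6 interval sets and BED12 gene models;
* a TSV differential-expression table with columns
  ``gene_id  log2FoldChange  padj``.

All positions are converted to the package-wide 0-based half-open convention
on read. Parse failures report the offending line number.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .core import GeneModel, GenomicInterval, ValidationError

CpGCall = Tuple[str, int, str, int, int]  # chrom, 0-based pos, strand, n_meth, n_unmeth


class ParseError(ValueError):
    """A malformed row in an input file; message carries the line number."""


@dataclass(frozen=True)
class DEGRecord:
    gene_id: str
    log2_fold_change: float
    adjusted_p: float
    direction: str  # up | down | none


def _fail(path, lineno: int, msg: str) -> None:
    raise ParseError(f"{path}:{lineno}: {msg}")


def read_cpg_calls(path, dialect: str = "bedgraph_counts") -> List[CpGCall]:
    """Read per-CpG methylation calls; returns rows sorted by (chrom, pos).

    ``dialect`` is ``bedgraph_counts`` (0-based) or ``cytosine_report``
    (1-based; shifted on read). Non-CpG-context rows in cytosine reports are
    skipped.
    """
    if dialect not in ("bedgraph_counts", "cytosine_report"):
        raise ValueError(f"unknown dialect {dialect!r}")
    calls: List[CpGCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                if dialect == "bedgraph_counts":
                    if len(fields) < 6:
                        _fail(path, lineno, f"expected >=6 columns, got {len(fields)}")
                    chrom, start = fields[0], int(fields[1])
                    n_meth, n_unmeth = int(fields[4]), int(fields[5])
                    strand = "+"
                    pos = start
                else:
                    if len(fields) < 5:
                        _fail(path, lineno, f"expected >=5 columns, got {len(fields)}")
                    chrom, pos1, strand = fields[0], int(fields[1]), fields[2]
                    n_meth, n_unmeth = int(fields[3]), int(fields[4])
                    if len(fields) >= 6 and fields[5] not in ("CG", "CpG"):
                        continue
                    pos = pos1 - 1
            except ValueError as exc:
                if isinstance(exc, ParseError):
                    raise
                _fail(path, lineno, f"malformed row: {exc}")
            if n_meth < 0 or n_unmeth < 0:
                raise ValidationError(f"{path}:{lineno}: negative count")
            if pos < 0:
                raise ValidationError(f"{path}:{lineno}: position < 1 (1-based)")
            if strand not in ("+", "-"):
                _fail(path, lineno, f"bad strand {strand!r}")
            calls.append((chrom, pos, strand, n_meth, n_unmeth))
    calls.sort(key=lambda c: (c[0], c[1]))
    return calls


def write_cpg_calls(calls: Sequence[CpGCall], path, scores=None) -> None:
    """Write calls as bedGraph-with-counts (one bp per CpG, + strand collapsed)."""
    rows = sorted(calls, key=lambda c: (c[0], c[1]))
    with open(path, "w") as fh:
        for chrom, pos, _strand, m, u in rows:
            pct = 100.0 * m / (m + u) if (m + u) > 0 else 0.0
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{pct:.4f}\t{m}\t{u}\n")


def read_bed(path) -> List[GenomicInterval]:
    """Read a 3-6 column BED file into validated half-open intervals."""
    out: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                _fail(path, lineno, f"expected >=3 columns, got {len(f)}")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                _fail(path, lineno, f"malformed coordinates: {exc}")
            name = f[3] if len(f) > 3 and f[3] != "." else None
            score: Optional[float] = None
            if len(f) > 4 and f[4] != ".":
                try:
                    score = float(f[4])
                except ValueError as exc:
                    _fail(path, lineno, f"malformed score: {exc}")
            strand = f[5] if len(f) > 5 else "."
            try:
                out.append(GenomicInterval(f[0], start, end, name, score, strand))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    """Write intervals as tab-separated BED sorted by (chrom, start, end).

    Optional columns are emitted only up to the last one any interval uses, so
    plain intervals round-trip byte-identically through :func:`read_bed`.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    ncols = 3
    for iv in ivs:
        if iv.strand != ".":
            ncols = 6
        elif iv.score is not None:
            ncols = max(ncols, 5)
        elif iv.name is not None:
            ncols = max(ncols, 4)
    with open(path, "w") as fh:
        for iv in ivs:
            f = [iv.chrom, str(iv.start), str(iv.end)]
            if ncols >= 4:
                f.append(iv.name if iv.name is not None else ".")
            if ncols >= 5:
                f.append("%g" % iv.score if iv.score is not None else ".")
            if ncols >= 6:
                f.append(iv.strand)
            fh.write("\t".join(f) + "\n")


def read_gene_models(path) -> List[GeneModel]:
    """Read gene models from BED12; CDS span taken from thickStart/thickEnd.

    ``thickStart == thickEnd`` marks a non-coding transcript.
    """
    genes: List[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                _fail(path, lineno, f"expected 12 BED12 columns, got {len(f)}")
            try:
                chrom, tx_start, tx_end = f[0], int(f[1]), int(f[2])
                gene_id, strand = f[3], f[5]
                thick_start, thick_end = int(f[6]), int(f[7])
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                _fail(path, lineno, f"malformed BED12 row: {exc}")
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                _fail(path, lineno, "blockCount disagrees with block lists")
            exon_starts = tuple(tx_start + o for o in offsets)
            exon_ends = tuple(s + sz for s, sz in zip(exon_starts, sizes))
            cds: Tuple[Optional[int], Optional[int]] = (
                (None, None)
                if thick_start == thick_end
                else (thick_start, thick_end)
            )
            try:
                genes.append(
                    GeneModel(
                        gene_id, chrom, strand, tx_start, tx_end,
                        cds[0], cds[1], exon_starts, exon_ends,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_models(genes: Sequence[GeneModel], path) -> None:
    """Write gene models as BED12 (inverse of :func:`read_gene_models`)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.tx_start, g.tx_end)):
            thick = (g.cds_start, g.cds_end) if g.is_coding else (g.tx_start, g.tx_start)
            sizes = ",".join(str(e - s) for s, e in zip(g.exon_starts, g.exon_ends))
            offsets = ",".join(str(s - g.tx_start) for s in g.exon_starts)
            fh.write(
                "\t".join(
                    [
                        g.chrom, str(g.tx_start), str(g.tx_end), g.gene_id, "0",
                        g.strand, str(thick[0]), str(thick[1]), "0",
                        str(len(g.exon_starts)), sizes, offsets,
                    ]
                )
                + "\n"
            )


def read_deg_table(path, alpha: float = 0.05) -> List[DEGRecord]:
    """Read a DEG TSV (gene_id, log2FoldChange, padj) and assign directions.

    ``direction`` is the sign of the fold change when ``padj < alpha``, else
    ``none``; genes with missing padj are treated as not significant.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2FoldChange", "padj"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    out: List[DEGRecord] = []
    for row in df.itertuples(index=False):
        padj = float(row.padj) if pd.notna(row.padj) else 1.0
        if not (0.0 <= padj <= 1.0):
            raise ValidationError(f"{path}: padj out of [0,1] for {row.gene_id}")
        lfc = float(row.log2FoldChange)
        if padj < alpha and lfc != 0:
            direction = "up" if lfc > 0 else "down"
        else:
            direction = "none"
        out.append(DEGRecord(str(row.gene_id), lfc, padj, direction))
    return out


def write_deg_table(records: Sequence[DEGRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["gene_id", "log2FoldChange", "padj"])
        for r in records:
            w.writerow([r.gene_id, f"{r.log2_fold_change:.6g}", f"{r.adjusted_p:.6g}"])


def read_chrom_sizes(path) -> dict:
    """Read a two-column ``chrom<TAB>size`` file."""
    sizes = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.split()
            if len(f) < 2:
                _fail(path, lineno, "expected 'chrom size'")
            sizes[f[0]] = int(f[1])
    return sizes


def write_chrom_sizes(sizes: dict, path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")
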