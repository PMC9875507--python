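"""Core genomic value types.

Every coordinate in the package is 0-based half-open (BED convention).
Inputs in 1-based conventions (cytosine reports) are shifted on read, so
downstream code never sees more than one convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence


class ValidationError(ValueError):
    """Raised when a domain invariant is violated by an input."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``.

    ``name``, ``score`` and ``strand`` mirror BED columns 4-6 and are
    optional; ``strand`` is one of ``+``, ``-`` or ``.``.
    """

    chrom: str
    start: int
    end: int
    name: Optional[str] = field(default=None, compare=False)
    score: Optional[float] = field(default=None, compare=False)
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"interval end must exceed start: [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A transcript model with half-open exon and CDS spans.

    ``cds_start``/``cds_end`` are ``None`` for non-coding transcripts.
    Exons are sorted, non-overlapping, and contained in the transcript span.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: Optional[int]
    cds_end: Optional[int]
    exon_starts: tuple
    exon_ends: tuple

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        if not (0 <= self.tx_start < self.tx_end):
            raise ValidationError(f"gene {self.gene_id}: bad transcript span")
        if len(self.exon_starts) != len(self.exon_ends) or not self.exon_starts:
            raise ValidationError(f"gene {self.gene_id}: malformed exon lists")
        prev_end = None
        for s, e in zip(self.exon_starts, self.exon_ends):
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValidationError(
                    f"gene {self.gene_id}: exon [{s}, {e}) outside transcript span"
                )
            if prev_end is not None and s < prev_end:
                raise ValidationError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValidationError(f"gene {self.gene_id}: half-specified CDS")
        if self.cds_start is not None:
            if not (self.tx_start <= self.cds_start < self.cds_end <= self.tx_end):
                raise ValidationError(f"gene {self.gene_id}: CDS outside transcript")

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def tss(self) -> int:
        """Transcription start site position (strand-aware)."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    def exons(self) -> list:
        return [
            GenomicInterval(self.chrom, s, e, name=self.gene_id, strand=self.strand)
            for s, e in zip(self.exon_starts, self.exon_ends)
        ]


def check_chrom_names(*interval_sets: Sequence[GenomicInterval]) -> None:
    """Preflight check that all inputs agree on chromosome naming.

    Chromosome names are compared by exact string match (no ``chr`` aliasing);
    a disjoint name set between two non-empty inputs almost always means an
    assembly or naming mismatch and is reported instead of silently yielding
    zero overlaps.
    """
    name_sets = [
        {iv.chrom for iv in ivs} for ivs in interval_sets if len(ivs) > 0
    ]
    for i in range(1, len(name_sets)):
        if name_sets[0].isdisjoint(name_sets[i]):
            raise ValidationError(
                "chromosome name sets are disjoint between inputs: "
                f"{sorted(name_sets[0])[:5]} vs {sorted(name_sets[i])[:5]}"
            )
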