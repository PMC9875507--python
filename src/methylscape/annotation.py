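"""Seven-feature genome annotation derived from gene models.

Features: ``distal_promoter`` (1-5 kb upstream of the TSS, strand-aware),
``proximal_promoter`` (1 kb upstream), ``utr5``, ``exon`` (coding exon bp;
whole exons for non-coding transcripts), ``intron``, ``utr3``, and
``intergenic`` (everything else). A region is annotated with *every* feature
it overlaps by >= 1 bp and counted once per feature, so feature counts over a
region set can exceed the number of regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

from .core import GeneModel, GenomicInterval, ValidationError
from . import intervalops

FEATURES = (
    "distal_promoter",
    "proximal_promoter",
    "utr5",
    "exon",
    "intron",
    "utr3",
    "intergenic",
)

PROXIMAL_PROMOTER_BP = 1000
DISTAL_PROMOTER_BP = 5000


@dataclass
class FeatureMap:
    """Per-feature interval sets, each interval tagged with its source gene."""

    features: Dict[str, List[Tuple[GenomicInterval, Optional[str]]]]
    chrom_sizes: Mapping[str, int]

    def intervals(self, feature: str) -> List[GenomicInterval]:
        return [iv for iv, _ in self.features[feature]]


@dataclass(frozen=True)
class AnnotatedRegion:
    interval: GenomicInterval
    features: FrozenSet[str]
    genes: FrozenSet[str]

    def __post_init__(self) -> None:
        if not self.features:
            raise ValidationError("annotated region must carry at least one feature")


def _clip(chrom: str, start: int, end: int, size: int) -> Optional[GenomicInterval]:
    s, e = max(0, start), min(size, end)
    return GenomicInterval(chrom, s, e) if s < e else None


def build_feature_map(
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    proximal_bp: int = PROXIMAL_PROMOTER_BP,
    distal_bp: int = DISTAL_PROMOTER_BP,
) -> FeatureMap:
    """Derive the seven-feature annotation from gene models (strand-aware).

    Each transcript contributes its features independently; ``intergenic`` is
    the genome complement of everything gene-linked.
    """
    feats: Dict[str, List[Tuple[GenomicInterval, Optional[str]]]] = {
        f: [] for f in FEATURES
    }
    for g in genes:
        if g.chrom not in chrom_sizes:
            raise ValidationError(f"gene {g.gene_id}: unknown chromosome {g.chrom}")
        size = chrom_sizes[g.chrom]
        if g.tx_end > size:
            raise ValidationError(f"gene {g.gene_id} extends beyond end of {g.chrom}")

        if g.strand == "+":
            prox = _clip(g.chrom, g.tx_start - proximal_bp, g.tx_start, size)
            dist = _clip(g.chrom, g.tx_start - distal_bp, g.tx_start - proximal_bp, size)
        else:
            prox = _clip(g.chrom, g.tx_end, g.tx_end + proximal_bp, size)
            dist = _clip(g.chrom, g.tx_end + proximal_bp, g.tx_end + distal_bp, size)
        if prox:
            feats["proximal_promoter"].append((prox, g.gene_id))
        if dist:
            feats["distal_promoter"].append((dist, g.gene_id))

        exons = g.exons()
        tx = GenomicInterval(g.chrom, g.tx_start, g.tx_end)
        for intron in intervalops.subtract([tx], exons):
            feats["intron"].append((intron, g.gene_id))
        if g.is_coding:
            cds = GenomicInterval(g.chrom, g.cds_start, g.cds_end)
            if g.strand == "+":
                up = (g.tx_start, g.cds_start)
                down = (g.cds_end, g.tx_end)
            else:
                up = (g.cds_end, g.tx_end)
                down = (g.tx_start, g.cds_start)
            for label, (s, e) in (("utr5", up), ("utr3", down)):
                if s < e:
                    span = [GenomicInterval(g.chrom, s, e)]
                    for piece in intervalops.intersect_pieces(exons, span):
                        feats[label].append((piece, g.gene_id))
            for piece in intervalops.intersect_pieces(exons, [cds]):
                feats["exon"].append((piece, g.gene_id))
        else:
            for ex in exons:
                feats["exon"].append(
                    (GenomicInterval(g.chrom, ex.start, ex.end), g.gene_id)
                )

    gene_linked = [iv for f in FEATURES[:-1] for iv, _ in feats[f]]
    for piece in intervalops.complement(gene_linked, chrom_sizes):
        feats["intergenic"].append((piece, None))
    return FeatureMap(feats, dict(chrom_sizes))


def annotate_regions(
    regions: Sequence[GenomicInterval], fmap: FeatureMap
) -> List[AnnotatedRegion]:
    """Attach every overlapped feature label (and its genes) to each region.

    Regions overlapping no gene-linked feature get ``{intergenic}``.
    """
    feature_sets: List[set] = [set() for _ in regions]
    gene_sets: List[set] = [set() for _ in regions]
    for feature in FEATURES:
        items = fmap.features[feature]
        ivs = [iv for iv, _ in items]
        for ri, fi in intervalops.overlap_pairs(regions, ivs):
            feature_sets[ri].add(feature)
            gene_id = items[fi][1]
            if gene_id is not None:
                gene_sets[ri].add(gene_id)
    out = []
    for region, fs, gs in zip(regions, feature_sets, gene_sets):
        if not fs:
            fs = {"intergenic"}
        out.append(AnnotatedRegion(region, frozenset(fs), frozenset(gs)))
    return out


def feature_count_table(annotated: Sequence[AnnotatedRegion]) -> Dict[str, int]:
    """Regions per feature; a multi-feature region counts once in each."""
    counts = {f: 0 for f in FEATURES}
    for a in annotated:
        for f in a.features:
            counts[f] += 1
    return counts
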