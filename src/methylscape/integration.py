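"""Cross-analyses of methylation, chromatin accessibility, ChIP peaks and DEGs.

Covers peak specificity between compartments, replicate peak merging,
chromatin-state construction (opening / closing / stable_open /
stable_closed, an exact genome partition), DMR-by-state cross-tabulation,
DMAR calling (DMR x DAR intersections), DEG association, transcription-factor
peak classification by open/closed chromatin, and peak x UMR/LMR
cross-tabulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import GenomicInterval, ValidationError
from . import intervalops
from .annotation import FEATURES, FeatureMap, annotate_regions
from .dmr import DMR
from .io import DEGRecord
from .segmentation import MethylRegion

STATE_TIE_ORDER = ("opening", "closing", "stable_open", "stable_closed")


@dataclass(frozen=True)
class PeakSpecificity:
    peak: GenomicInterval
    specificity: str  # epithelium_specific | fiber_specific | shared


@dataclass(frozen=True)
class DMAR:
    """A differentially methylated and accessible region (DMR x DAR overlap)."""

    region: GenomicInterval  # the bp intersection of the pair
    dmr: DMR
    dar: GenomicInterval
    dar_direction: str  # opening | closing
    features: FrozenSet[str] = frozenset()
    genes: FrozenSet[str] = frozenset()
    deg_direction: str = "no_gene"  # up | down | none | no_gene


def intersect_sets(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    mode: str = "any_overlap",
):
    """bedtools-style intersection of two interval sets.

    ``any_overlap`` returns ``(i, j)`` index pairs of intervals overlapping by
    >= 1 bp; ``intersection_pieces`` returns the bp-intersection intervals.
    """
    if mode == "any_overlap":
        return intervalops.overlap_pairs(a, b)
    if mode == "intersection_pieces":
        return intervalops.intersect_pieces(a, b)
    raise ValueError(f"unknown mode {mode!r}")


def merge_replicate_peaks(
    rep1: Sequence[GenomicInterval], rep2: Sequence[GenomicInterval]
) -> List[GenomicInterval]:
    """A compartment's peak set: bp supported by both biological replicates."""
    return intervalops.intersect_pieces(rep1, rep2)


def classify_peak_specificity(
    epi_peaks: Sequence[GenomicInterval], fib_peaks: Sequence[GenomicInterval]
) -> List[PeakSpecificity]:
    """Split compartment peak sets into epithelium-specific / fiber-specific / shared.

    Specific peaks are input peaks with no overlap in the other compartment;
    shared peaks are the merged union pieces covered by both compartments.
    """
    out: List[PeakSpecificity] = []
    epi_hit = intervalops.overlaps_any(epi_peaks, fib_peaks)
    fib_hit = intervalops.overlaps_any(fib_peaks, epi_peaks)
    for peak, hit in zip(epi_peaks, epi_hit):
        if not hit:
            out.append(PeakSpecificity(peak, "epithelium_specific"))
    for peak, hit in zip(fib_peaks, fib_hit):
        if not hit:
            out.append(PeakSpecificity(peak, "fiber_specific"))
    union = intervalops.merge(list(epi_peaks) + list(fib_peaks))
    both = np.array(intervalops.overlaps_any(union, epi_peaks)) & np.array(
        intervalops.overlaps_any(union, fib_peaks)
    )
    for piece, hit in zip(union, both):
        if hit:
            out.append(PeakSpecificity(piece, "shared"))
    return out


def chromatin_states(
    atac_peaks_a: Sequence[GenomicInterval],
    atac_peaks_b: Sequence[GenomicInterval],
    dars: Mapping[str, Sequence[GenomicInterval]],
    chrom_sizes: Mapping[str, int],
) -> Dict[str, List[GenomicInterval]]:
    """The four chromatin states of a differentiation path, partitioning the genome.

    ``stable_open`` is the bp intersection of the two endpoint conditions'
    ATAC peaks minus DAR bp; ``opening``/``closing`` are the DAR intervals
    themselves; ``stable_closed`` is the genome complement of stable open
    chromatin minus DAR bp. Overlapping opening and closing DARs are
    rejected as ill-formed input.
    """
    opening = list(dars.get("opening", []))
    closing = list(dars.get("closing", []))
    if intervalops.intersect_pieces(opening, closing):
        raise ValidationError("opening and closing DARs overlap; ill-formed input")
    all_dars = opening + closing
    stable_open = intervalops.subtract(
        intervalops.intersect_pieces(atac_peaks_a, atac_peaks_b), all_dars
    )
    stable_closed = intervalops.subtract(
        intervalops.complement(stable_open, chrom_sizes), all_dars
    )
    return {
        "opening": intervalops.merge(opening),
        "closing": intervalops.merge(closing),
        "stable_open": stable_open,
        "stable_closed": stable_closed,
    }


def assign_state(
    region: GenomicInterval, states: Mapping[str, Sequence[GenomicInterval]]
) -> str:
    """The state sharing the most bp with ``region``; ties break in the fixed
    order opening > closing > stable_open > stable_closed."""
    best, best_bp = None, -1
    for state in STATE_TIE_ORDER:
        bp = int(intervalops.overlap_bp_with([region], states[state])[0])
        if bp > best_bp:
            best, best_bp = state, bp
    return best


def crosstab_dmrs_by_state(
    dmrs: Sequence[DMR],
    states: Mapping[str, Sequence[GenomicInterval]],
    fmap: FeatureMap,
) -> pd.DataFrame:
    """Counts per (path, DMR direction, chromatin state, feature).

    Each DMR is assigned a single state by majority bp and counted once per
    overlapped feature (so summing counts over features for one row group
    gives the total feature-incidence, not the DMR count).
    """
    annos = annotate_regions([d.interval for d in dmrs], fmap)
    rows = []
    for d, anno in zip(dmrs, annos):
        state = assign_state(d.interval, states)
        for feat in sorted(anno.features):
            rows.append((d.path, d.direction, state, feat))
    df = pd.DataFrame(rows, columns=["path", "direction", "state", "feature"])
    if df.empty:
        return pd.DataFrame(columns=["path", "direction", "state", "feature", "count"])
    return (
        df.value_counts(["path", "direction", "state", "feature"])
        .rename("count")
        .reset_index()
        .sort_values(["path", "direction", "state", "feature"])
        .reset_index(drop=True)
    )


def call_dmars(
    dmrs: Sequence[DMR],
    dars: Mapping[str, Sequence[GenomicInterval]],
    fmap: Optional[FeatureMap] = None,
) -> List[DMAR]:
    """One DMAR per overlapping (DMR, DAR) pair, carrying both directions.

    The DMAR region is the bp intersection of the pair; features and genes
    come from annotating that region when a feature map is given.
    """
    out: List[DMAR] = []
    dmr_ivs = [d.interval for d in dmrs]
    for direction in ("opening", "closing"):
        dar_list = list(dars.get(direction, []))
        for i, j in intervalops.overlap_pairs(dmr_ivs, dar_list):
            dmr, dar = dmrs[i], dar_list[j]
            piece = GenomicInterval(
                dmr.interval.chrom,
                max(dmr.interval.start, dar.start),
                min(dmr.interval.end, dar.end),
            )
            out.append(DMAR(piece, dmr, dar, direction))
    if fmap is not None and out:
        annos = annotate_regions([x.region for x in out], fmap)
        out = [
            DMAR(x.region, x.dmr, x.dar, x.dar_direction, a.features, a.genes)
            for x, a in zip(out, annos)
        ]
    out.sort(key=lambda x: (x.region.chrom, x.region.start, x.region.end))
    return out


def associate_dmars_degs(
    dmars: Sequence[DMAR], deg_table: Sequence[DEGRecord]
) -> Tuple[List[DMAR], pd.DataFrame, pd.DataFrame]:
    """Label each DMAR with the expression direction of its associated gene.

    ``deg_direction`` is the DEG direction of an associated significant gene
    (``up`` preferred over ``down`` when several genes disagree), ``none``
    when genes are present but not significant, ``no_gene`` for regions with
    no gene link. Returns the labeled DMARs plus both count summaries: per
    DMAR category and per DEG.
    """
    deg_by_gene = {r.gene_id: r for r in deg_table}
    genes_in_dmars = {g for x in dmars for g in x.genes}
    if genes_in_dmars:
        missing = sum(1 for g in genes_in_dmars if g not in deg_by_gene)
        if missing / len(genes_in_dmars) > 0.5:
            raise ValidationError(
                f"{missing}/{len(genes_in_dmars)} DMAR genes absent from the DEG "
                "table; gene identifier spaces likely disagree"
            )
    labeled: List[DMAR] = []
    per_deg_rows = []
    for x in dmars:
        if not x.genes:
            direction = "no_gene"
        else:
            dirs = {
                deg_by_gene[g].direction for g in x.genes if g in deg_by_gene
            }
            direction = "up" if "up" in dirs else "down" if "down" in dirs else "none"
        labeled.append(
            DMAR(x.region, x.dmr, x.dar, x.dar_direction, x.features, x.genes, direction)
        )
        for g in x.genes:
            if g in deg_by_gene:
                per_deg_rows.append(
                    (g, deg_by_gene[g].direction, x.dmr.direction, x.dar_direction)
                )
    cat_rows = [
        (x.dmr.path, x.dmr.direction, x.dar_direction, x.deg_direction)
        for x in labeled
    ]
    per_dmar = (
        pd.DataFrame(
            cat_rows, columns=["path", "dmr_direction", "dar_direction", "deg_direction"]
        )
        .value_counts()
        .rename("count")
        .reset_index()
        if cat_rows
        else pd.DataFrame(
            columns=["path", "dmr_direction", "dar_direction", "deg_direction", "count"]
        )
    )
    per_deg = (
        pd.DataFrame(
            per_deg_rows,
            columns=["gene_id", "deg_direction", "dmr_direction", "dar_direction"],
        )
        .drop_duplicates()
        .value_counts(["deg_direction", "dmr_direction", "dar_direction"])
        .rename("n_genes")
        .reset_index()
        if per_deg_rows
        else pd.DataFrame(
            columns=["deg_direction", "dmr_direction", "dar_direction", "n_genes"]
        )
    )
    return labeled, per_dmar, per_deg


def classify_tf_peaks_by_chromatin(
    tf_peaks: Sequence[GenomicInterval],
    merged_atac_peaks: Sequence[GenomicInterval],
) -> Dict[str, List[GenomicInterval]]:
    """Partition TF peaks into open- vs closed-chromatin-associated.

    A peak is ``open_associated`` when it overlaps >= 1 bp of the merged
    ATAC peak set; the remainder are ``closed_associated``.
    """
    hit = intervalops.overlaps_any(tf_peaks, merged_atac_peaks)
    return {
        "open_associated": [p for p, h in zip(tf_peaks, hit) if h],
        "closed_associated": [p for p, h in zip(tf_peaks, hit) if not h],
    }


def peak_umr_lmr_crosstab(
    tf_peaks: Sequence[GenomicInterval],
    umr_lmr_by_compartment: Mapping[str, Sequence[MethylRegion]],
    fmap: FeatureMap,
) -> pd.DataFrame:
    """Peaks by compartment-specificity of overlapped UMR/LMR bp, by feature.

    Rows: ``epithelium`` (peak overlaps epithelium UMR/LMR bp only),
    ``fiber`` (fiber only), ``shared`` (both), ``no_umr_lmr`` (neither);
    columns: the seven genomic features under the once-per-feature counting
    rule. Row totals over *peaks* (not feature incidences) partition the
    input peak set.
    """
    compartments = list(umr_lmr_by_compartment)
    if set(compartments) != {"epithelium", "fiber"}:
        raise ValidationError("expected UMR/LMR sets for 'epithelium' and 'fiber'")
    hits = {
        comp: intervalops.overlaps_any(
            tf_peaks, [r.interval for r in umr_lmr_by_compartment[comp]]
        )
        for comp in compartments
    }
    annos = annotate_regions(list(tf_peaks), fmap)
    table = {
        row: {f: 0 for f in FEATURES}
        for row in ("epithelium", "fiber", "shared", "no_umr_lmr")
    }
    row_of_peak = []
    for i in range(len(tf_peaks)):
        e, f = bool(hits["epithelium"][i]), bool(hits["fiber"][i])
        row = "shared" if (e and f) else "epithelium" if e else "fiber" if f else "no_umr_lmr"
        row_of_peak.append(row)
        for feat in annos[i].features:
            table[row][feat] += 1
    df = pd.DataFrame(table).T.loc[["epithelium", "fiber", "shared", "no_umr_lmr"], list(FEATURES)]
    df["n_peaks"] = [row_of_peak.count(r) for r in df.index]
    return df
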