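"""Hypomethylated-region segmentation and UMR/LMR classification.

Candidate regions are maximal runs of consecutive CpGs whose *smoothed*
score falls below a cutoff (default 0.50), with nearby runs merged and short
runs discarded. Candidates are then classified on the *raw* per-CpG score
median:

* UMR (unmethylated region): more than 32 CpGs, median methylation < 20%;
* LMR (low-methylated region): fewer than 32 CpGs, median in [20%, 50%);
* anything else (including exactly 32 CpGs) is left unclassified.

Both inequalities on the CpG count are strict, so the 32-CpG boundary falls
through to ``unclassified`` by design. Replicate-reproducible sets are the
base-pair intersection of same-class regions present in every replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from .core import GenomicInterval, ValidationError
from . import intervalops
from .methylome import CpGMethylome

UMR_LMR_CPG_THRESHOLD = 32
UMR_MEDIAN_MAX = 0.20
LMR_MEDIAN_MIN = 0.20
LMR_MEDIAN_MAX = 0.50


@dataclass(frozen=True)
class MethylRegion:
    """A candidate hypomethylated region with its classification."""

    interval: GenomicInterval
    n_cpgs: int
    median_meth: float
    klass: str  # UMR | LMR | unclassified
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.klass not in ("UMR", "LMR", "unclassified"):
            raise ValidationError(f"unknown region class {self.klass!r}")
        if self.n_cpgs < 1:
            raise ValidationError("region must contain at least one CpG")


def classify(n_cpgs: int, median_meth: float) -> str:
    """Apply the UMR/LMR thresholds to a (CpG count, median) pair."""
    if n_cpgs > UMR_LMR_CPG_THRESHOLD and median_meth < UMR_MEDIAN_MAX:
        return "UMR"
    if n_cpgs < UMR_LMR_CPG_THRESHOLD and LMR_MEDIAN_MIN <= median_meth < LMR_MEDIAN_MAX:
        return "LMR"
    return "unclassified"


def segment_hypomethylated(
    m: CpGMethylome,
    meth_cutoff: float = 0.50,
    min_cpgs: int = 4,
    max_gap_bp: int = 500,
) -> List[GenomicInterval]:
    """Maximal runs of consecutive CpGs with smoothed score below ``meth_cutoff``.

    Runs separated by <= ``max_gap_bp`` (between boundary CpGs) are merged;
    merged runs with fewer than ``min_cpgs`` CpGs are discarded. Region bounds
    run from the first to the last contributing CpG (half-open end at last
    position + 1).
    """
    if not m.is_smoothed:
        raise ValidationError("segmentation requires a smoothed methylome")
    out: List[GenomicInterval] = []
    for chrom in sorted(m.chroms):
        sites = m.chroms[chrom]
        below = sites.smoothed < meth_cutoff
        runs: List[List[int]] = []  # [first_idx, last_idx]
        start = None
        for i, flag in enumerate(below):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                runs.append([start, i - 1])
                start = None
        if start is not None:
            runs.append([start, len(below) - 1])
        merged: List[List[int]] = []
        for run in runs:
            if merged and sites.pos[run[0]] - sites.pos[merged[-1][1]] <= max_gap_bp:
                merged[-1][1] = run[1]
            else:
                merged.append(run)
        for first, last in merged:
            if last - first + 1 >= min_cpgs:
                out.append(
                    GenomicInterval(
                        chrom, int(sites.pos[first]), int(sites.pos[last]) + 1
                    )
                )
    return out


def _region_raw_stats(m: CpGMethylome, region: GenomicInterval):
    sites = m.chroms.get(region.chrom)
    if sites is None:
        return 0, np.nan
    lo = int(np.searchsorted(sites.pos, region.start, side="left"))
    hi = int(np.searchsorted(sites.pos, region.end, side="left"))
    raw = sites.raw_score[lo:hi]
    covered = raw[~np.isnan(raw)]
    return hi - lo, (float(np.median(covered)) if len(covered) else np.nan)


def classify_umr_lmr(
    region: GenomicInterval, m: CpGMethylome, sample_id: str = ""
) -> MethylRegion:
    """Classify one candidate region from the raw scores of its covered CpGs."""
    n_cpgs, median = _region_raw_stats(m, region)
    if n_cpgs == 0 or np.isnan(median):
        raise ValidationError(
            f"region {region.chrom}:{region.start}-{region.end} has no covered CpG"
        )
    return MethylRegion(region, n_cpgs, median, classify(n_cpgs, median), sample_id)


def call_umrs_lmrs(
    m: CpGMethylome,
    meth_cutoff: float = 0.50,
    min_cpgs: int = 4,
    max_gap_bp: int = 500,
) -> List[MethylRegion]:
    """Segment and classify one sample; drops candidates with no covered CpG."""
    out = []
    for region in segment_hypomethylated(m, meth_cutoff, min_cpgs, max_gap_bp):
        try:
            out.append(classify_umr_lmr(region, m, m.sample_id))
        except ValidationError:
            continue
    return out


def reproducible_regions(
    per_replicate_regions: Sequence[Sequence[MethylRegion]],
    reference: CpGMethylome = None,
) -> List[MethylRegion]:
    """Base-pair intersection of same-class regions present in all replicates.

    A reproducible region is bp covered (with >= 1 bp chained overlap) by a
    region of the same class in every replicate. CpG count and median are
    recomputed on the intersected span from the first replicate when a
    ``reference`` methylome is given; otherwise they are carried from the
    first replicate's overlapping region.
    """
    n_replicates = len(per_replicate_regions)
    if n_replicates < 2:
        warnings.warn("fewer than 2 replicates; returning input unchanged", stacklevel=2)
        return list(per_replicate_regions[0]) if per_replicate_regions else []
    out: List[MethylRegion] = []
    for klass in ("UMR", "LMR"):
        sets = [
            [r.interval for r in reps if r.klass == klass]
            for reps in per_replicate_regions
        ]
        pieces = intervalops.intersect_n_way(sets)
        rep1 = [r for r in per_replicate_regions[0] if r.klass == klass]
        for piece in pieces:
            if reference is not None:
                n_cpgs, median = _region_raw_stats(reference, piece)
                if n_cpgs == 0:
                    continue
            else:
                src = next(r for r in rep1 if r.interval.overlaps(piece))
                n_cpgs, median = src.n_cpgs, src.median_meth
            out.append(MethylRegion(piece, max(n_cpgs, 1), median, klass, "reproducible"))
    out.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end))
    return out


def regions_to_bed(regions: Sequence[MethylRegion]) -> List[GenomicInterval]:
    """BED6 form: name = class, score = round(1000 x median methylation)."""
    return [
        GenomicInterval(
            r.interval.chrom,
            r.interval.start,
            r.interval.end,
            name=r.klass,
            score=float(round(1000 * r.median_meth)),
            strand=".",
        )
        for r in regions
    ]


def regions_by_class(regions: Sequence[MethylRegion]) -> Dict[str, List[MethylRegion]]:
    out: Dict[str, List[MethylRegion]] = {"UMR": [], "LMR": [], "unclassified": []}
    for r in regions:
        out[r.klass].append(r)
    return out
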