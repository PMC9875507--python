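"""Differentially methylated region calling between two replicate groups.

A signal-to-noise statistic is computed per CpG from smoothed replicate
methylomes: ``t = (mean_advanced - mean_early) / sd_pool``, where ``sd_pool``
is the within-group replicate standard deviation pooled across groups,
averaged over a 1 kb local window, and floored at its genome-wide 75th
percentile so invariant sites cannot inflate the statistic. Candidate DMRs
are maximal runs of CpGs beyond symmetric empirical quantile cutoffs of the
t distribution; runs are kept when they hold enough CpGs and a large enough
mean methylation difference. ``hyper``/``hypo`` is the sign of the change
from the early to the advanced state of a differentiation path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .core import GenomicInterval, ValidationError
from .methylome import CpGMethylome

DEFAULT_MIN_COVERAGE = 4
SD_WINDOW_BP = 1000
SD_FLOOR_QUANTILE = 0.75

#: The four differentiation-path contrasts: (early, advanced) condition keys,
#: each a (compartment, stage) pair.
PATHS: Dict[str, Tuple[Tuple[str, str], Tuple[str, str]]] = {
    "Epi(dif)": (("epithelium", "E14.5"), ("epithelium", "P0.5")),
    "EpiFiber(dif)": (("epithelium", "E14.5"), ("fiber", "E14.5")),
    "Fiber(dif)": (("fiber", "E14.5"), ("fiber", "P0.5")),
    "Epi(E14.5)->Fiber(P0.5)": (("epithelium", "E14.5"), ("fiber", "P0.5")),
}


@dataclass(frozen=True)
class DMR:
    interval: GenomicInterval
    path: str
    direction: str  # hyper | hypo
    n_cpgs: int
    mean_diff: float  # advanced minus early, in [-1, 1]
    area_stat: float  # sum of per-CpG t over the region

    def __post_init__(self) -> None:
        if self.direction not in ("hyper", "hypo"):
            raise ValidationError(f"bad DMR direction {self.direction!r}")
        if (self.mean_diff > 0) != (self.direction == "hyper"):
            raise ValidationError("DMR direction must match the sign of mean_diff")


@dataclass
class TStatistics:
    """Per-CpG t statistics over the sites usable in both groups."""

    chroms: Dict[str, dict]  # chrom -> {pos, t, mean_diff}
    sd_floor: float

    def all_t(self) -> np.ndarray:
        if not self.chroms:
            return np.array([])
        return np.concatenate([c["t"] for c in self.chroms.values()])


def _group_arrays(group: Sequence[CpGMethylome], chrom: str, positions: np.ndarray):
    """Smoothed scores and coverages at ``positions`` for each replicate."""
    sm = np.empty((len(positions), len(group)))
    cov = np.empty((len(positions), len(group)), dtype=np.int64)
    for j, m in enumerate(group):
        s = m.chroms[chrom]
        idx = np.searchsorted(s.pos, positions)
        sm[:, j] = s.smoothed[idx]
        cov[:, j] = s.coverage[idx]
    return sm, cov


def _local_mean(pos: np.ndarray, values: np.ndarray, half_bp: float) -> np.ndarray:
    """Mean of ``values`` over sites within ``half_bp`` of each position."""
    lo = np.searchsorted(pos, pos - half_bp, side="left")
    hi = np.searchsorted(pos, pos + half_bp, side="right")
    csum = np.concatenate([[0.0], np.cumsum(values)])
    return (csum[hi] - csum[lo]) / np.maximum(hi - lo, 1)


def per_cpg_t_statistic(
    group_a: Sequence[CpGMethylome],
    group_b: Sequence[CpGMethylome],
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> TStatistics:
    """t statistics per CpG between early (a) and advanced (b) replicate groups.

    Only CpGs with coverage >= ``min_coverage`` in every replicate of both
    groups enter; swapping the groups negates every t.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs at least 2 replicates")
    for m in list(group_a) + list(group_b):
        if not m.is_smoothed:
            raise ValidationError(f"methylome {m.sample_id} is not smoothed")
    chroms = sorted(
        set.intersection(*(set(m.chroms) for m in list(group_a) + list(group_b)))
    )
    per_chrom: Dict[str, dict] = {}
    all_local_sd = []
    for chrom in chroms:
        common = group_a[0].chroms[chrom].pos
        for m in list(group_a) + list(group_b):
            common = np.intersect1d(common, m.chroms[chrom].pos, assume_unique=True)
        if len(common) == 0:
            continue
        sm_a, cov_a = _group_arrays(group_a, chrom, common)
        sm_b, cov_b = _group_arrays(group_b, chrom, common)
        ok = (cov_a.min(axis=1) >= min_coverage) & (cov_b.min(axis=1) >= min_coverage)
        pos = common[ok]
        if len(pos) == 0:
            continue
        sm_a, sm_b = sm_a[ok], sm_b[ok]
        mean_a, mean_b = sm_a.mean(axis=1), sm_b.mean(axis=1)
        sd_a, sd_b = sm_a.std(axis=1, ddof=1), sm_b.std(axis=1, ddof=1)
        pooled = np.sqrt((sd_a**2 + sd_b**2) / 2.0)
        local_sd = _local_mean(pos, pooled, SD_WINDOW_BP / 2.0)
        per_chrom[chrom] = {
            "pos": pos,
            "mean_diff": mean_b - mean_a,
            "local_sd": local_sd,
        }
        all_local_sd.append(local_sd)
    if not per_chrom:
        raise ValidationError("no CpG passes the coverage filter in both groups")
    floor = float(np.quantile(np.concatenate(all_local_sd), SD_FLOOR_QUANTILE))
    for chrom, d in per_chrom.items():
        denom = np.maximum(d["local_sd"], floor)
        denom = np.where(denom > 0, denom, np.inf)
        d["t"] = d["mean_diff"] / denom
        del d["local_sd"]
    return TStatistics(per_chrom, floor)


def call_dmrs(
    t_stats: TStatistics,
    path: str = "",
    quantile_cutoff: float = 0.975,
    min_cpgs: int = 3,
    min_mean_diff: float = 0.10,
) -> List[DMR]:
    """Candidate regions from runs of extreme t, filtered on size and effect.

    Cutoffs are the symmetric empirical quantiles (1 - q, q) of the pooled t
    distribution. A degenerate (constant) t distribution yields no DMRs.
    """
    t_all = t_stats.all_t()
    if len(t_all) == 0:
        return []
    if np.allclose(t_all, t_all[0]):
        warnings.warn("degenerate t distribution; no DMRs called", stacklevel=2)
        return []
    cut_hi = float(np.quantile(t_all, quantile_cutoff))
    cut_lo = float(np.quantile(t_all, 1.0 - quantile_cutoff))
    out: List[DMR] = []
    for chrom in sorted(t_stats.chroms):
        d = t_stats.chroms[chrom]
        pos, t, md = d["pos"], d["t"], d["mean_diff"]
        for sign, mask in (("hyper", t > cut_hi), ("hypo", t < cut_lo)):
            start = None
            boundaries = []
            for i, flag in enumerate(mask):
                if flag and start is None:
                    start = i
                elif not flag and start is not None:
                    boundaries.append((start, i - 1))
                    start = None
            if start is not None:
                boundaries.append((start, len(mask) - 1))
            for first, last in boundaries:
                n = last - first + 1
                if n < min_cpgs:
                    continue
                mean_diff = float(md[first : last + 1].mean())
                if abs(mean_diff) < min_mean_diff:
                    continue
                direction = "hyper" if mean_diff > 0 else "hypo"
                if direction != sign:
                    continue
                out.append(
                    DMR(
                        GenomicInterval(chrom, int(pos[first]), int(pos[last]) + 1),
                        path,
                        direction,
                        n,
                        mean_diff,
                        float(t[first : last + 1].sum()),
                    )
                )
    out.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end))
    return out


def dmr_paths(
    groups: Mapping[Tuple[str, str], Sequence[CpGMethylome]],
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    quantile_cutoff: float = 0.975,
    min_cpgs: int = 3,
    min_mean_diff: float = 0.10,
) -> Dict[str, List[DMR]]:
    """DMR sets for the four differentiation-path contrasts.

    ``groups`` maps (compartment, stage) keys -- e.g. ``("fiber", "P0.5")`` --
    to replicate methylomes. Each path is oriented early -> advanced.
    """
    out: Dict[str, List[DMR]] = {}
    for path, (early, advanced) in PATHS.items():
        for key in (early, advanced):
            if key not in groups:
                raise ValidationError(f"missing condition {key} for path {path}")
        ts = per_cpg_t_statistic(groups[early], groups[advanced], min_coverage)
        out[path] = call_dmrs(ts, path, quantile_cutoff, min_cpgs, min_mean_diff)
    return out
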