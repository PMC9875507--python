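"""Per-sample CpG methylomes: strand collapsing, scoring, smoothing, sampling, PCA.

The central object is :class:`CpGMethylome`, per-chromosome sorted arrays of
CpG positions with methylated/unmethylated read counts. The raw methylation
score at a CpG is ``n_meth / (n_meth + n_unmeth)``, undefined (NaN) at
uncovered sites. Smoothing is a BSmooth-style local weighted mean: for each
CpG the smallest centered window spanning at least ``min_window_bp`` and
containing at least ``min_cpgs`` CpGs, with tricube distance weights
multiplied by per-site coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.decomposition import PCA

from .core import ValidationError
from .io import CpGCall

DEFAULT_MIN_WINDOW_BP = 1000
DEFAULT_MIN_CPGS = 70


@dataclass
class ChromSites:
    pos: np.ndarray        # int64, strictly increasing
    n_meth: np.ndarray     # int64 >= 0
    n_unmeth: np.ndarray   # int64 >= 0
    smoothed: Optional[np.ndarray] = None  # float in [0,1], NaN if undefined

    def __post_init__(self) -> None:
        if len(self.pos) and np.any(np.diff(self.pos) <= 0):
            raise ValidationError("CpG positions must be strictly increasing")

    @property
    def coverage(self) -> np.ndarray:
        return self.n_meth + self.n_unmeth

    @property
    def raw_score(self) -> np.ndarray:
        cov = self.coverage
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov > 0, self.n_meth / np.maximum(cov, 1), np.nan)


@dataclass
class CpGMethylome:
    """All CpG sites of one sample, grouped by chromosome."""

    sample_id: str
    condition: str = ""
    replicate: int = 1
    chroms: Dict[str, ChromSites] = field(default_factory=dict)
    smoothing_flags: Dict[str, str] = field(default_factory=dict)

    @property
    def is_smoothed(self) -> bool:
        return all(c.smoothed is not None for c in self.chroms.values())

    def n_sites(self) -> int:
        return sum(len(c.pos) for c in self.chroms.values())


def methylation_score(n_meth: int, n_unmeth: int) -> float:
    """Raw CpG methylation score; NaN when the site has no coverage."""
    if n_meth < 0 or n_unmeth < 0:
        raise ValidationError("counts must be non-negative")
    cov = n_meth + n_unmeth
    return n_meth / cov if cov > 0 else float("nan")


def collapse_strands(calls: Sequence[CpGCall]) -> Dict[str, ChromSites]:
    """Collapse plus/minus strand calls onto the + strand C of each CpG.

    A minus-strand call at position ``p`` belongs to the CpG whose + strand C
    sits at ``p - 1``; counts from the two strands are summed. Total counts
    are conserved.
    """
    acc: Dict[str, Dict[int, List[int]]] = {}
    for chrom, pos, strand, m, u in calls:
        if strand == "-":
            if pos < 1:
                raise ValidationError(
                    f"minus-strand call at {chrom}:{pos} has no possible partner"
                )
            pos = pos - 1
        site = acc.setdefault(chrom, {}).setdefault(pos, [0, 0])
        site[0] += m
        site[1] += u
    out: Dict[str, ChromSites] = {}
    for chrom in sorted(acc):
        positions = np.array(sorted(acc[chrom]), dtype=np.int64)
        nm = np.array([acc[chrom][p][0] for p in positions], dtype=np.int64)
        nu = np.array([acc[chrom][p][1] for p in positions], dtype=np.int64)
        out[chrom] = ChromSites(positions, nm, nu)
    return out


def methylome_from_calls(
    calls: Sequence[CpGCall], sample_id: str, condition: str = "", replicate: int = 1
) -> CpGMethylome:
    return CpGMethylome(sample_id, condition, replicate, collapse_strands(calls))


def _tricube(x: np.ndarray) -> np.ndarray:
    x = np.clip(np.abs(x), 0.0, 1.0)
    return (1.0 - x**3) ** 3


def _smooth_kernel_py(pos, raw0, cov, lo0, hi0, min_cpgs, half, chrom_mean):
    n = len(pos)
    out = np.empty(n)
    for i in range(n):
        lo, hi = lo0[i], hi0[i]
        while hi - lo < min_cpgs:
            left_d = pos[i] - pos[lo - 1] if lo > 0 else np.inf
            right_d = pos[hi] - pos[i] if hi < n else np.inf
            if left_d <= right_d:
                lo -= 1
            else:
                hi += 1
        h = max(half, float(pos[i] - pos[lo]), float(pos[hi - 1] - pos[i])) + 1.0
        wsum = 0.0
        vsum = 0.0
        for k in range(lo, hi):
            x = abs(pos[k] - pos[i]) / h
            w = (1.0 - x * x * x) ** 3 * cov[k]
            wsum += w
            vsum += w * raw0[k]
        out[i] = vsum / wsum if wsum > 0 else chrom_mean
    return out


try:  # numba gives a ~20x faster inner loop when available
    from numba import njit

    _smooth_kernel = njit(fastmath=True)(_smooth_kernel_py)
except ImportError:  # pragma: no cover - exercised only without numba
    _smooth_kernel = _smooth_kernel_py


def _smooth_chrom(
    sites: ChromSites, min_window_bp: int, min_cpgs: int
) -> Tuple[np.ndarray, Optional[str]]:
    pos = sites.pos
    raw = sites.raw_score
    cov = sites.coverage.astype(float)
    n = len(pos)
    covered = cov > 0
    if covered.sum() == 0:
        return np.full(n, np.nan), "no covered CpGs"
    chrom_mean = float(np.average(raw[covered], weights=cov[covered]))
    if n < min_cpgs:
        return np.full(n, chrom_mean), f"fewer than {min_cpgs} CpGs; chromosome mean used"

    half = min_window_bp / 2.0
    lo0 = np.searchsorted(pos, pos - half, side="left").astype(np.int64)
    hi0 = np.searchsorted(pos, pos + half, side="right").astype(np.int64)
    out = _smooth_kernel(
        pos.astype(np.float64),
        np.nan_to_num(raw),
        cov,
        lo0,
        hi0,
        min_cpgs,
        half,
        chrom_mean,
    )
    return np.clip(out, 0.0, 1.0), None


def smooth_methylome(
    m: CpGMethylome,
    min_window_bp: int = DEFAULT_MIN_WINDOW_BP,
    min_cpgs: int = DEFAULT_MIN_CPGS,
) -> CpGMethylome:
    """Attach smoothed scores to every chromosome of ``m`` (in place, returned).

    Chromosomes with fewer than ``min_cpgs`` sites fall back to the
    coverage-weighted chromosome mean and are flagged in
    ``m.smoothing_flags``.
    """
    if min_window_bp <= 0 or min_cpgs <= 0:
        raise ValueError("smoothing parameters must be positive")
    for chrom, sites in m.chroms.items():
        smoothed, flag = _smooth_chrom(sites, min_window_bp, min_cpgs)
        sites.smoothed = smoothed
        if flag:
            m.smoothing_flags[chrom] = flag
            warnings.warn(f"{m.sample_id}/{chrom}: {flag}", stacklevel=2)
    return m


def shared_sites(methylomes: Sequence[CpGMethylome]) -> Dict[str, np.ndarray]:
    """Positions present in every methylome, per chromosome."""
    chroms = set.intersection(*(set(m.chroms) for m in methylomes))
    out = {}
    for chrom in sorted(chroms):
        common = methylomes[0].chroms[chrom].pos
        for m in methylomes[1:]:
            common = np.intersect1d(common, m.chroms[chrom].pos, assume_unique=True)
        out[chrom] = common
    return out


def sample_cpgs(
    methylomes: Sequence[CpGMethylome],
    n: int,
    seed: int,
    min_coverage: int = 1,
    use_smoothed: bool = False,
) -> Tuple[np.ndarray, List[Tuple[str, int]], List[str]]:
    """Uniformly sample up to ``n`` CpGs covered in all samples.

    Returns ``(matrix, sites, sample_ids)``: a ``len(sites) x n_samples``
    score matrix, the sampled ``(chrom, pos)`` list (sorted), and the sample
    ids in column order. Deterministic for a given ``seed``.
    """
    if not methylomes:
        raise ValueError("no methylomes given")
    eligible: List[Tuple[str, int]] = []
    index_maps = []
    for m in methylomes:
        index_maps.append(
            {chrom: {int(p): i for i, p in enumerate(s.pos)} for chrom, s in m.chroms.items()}
        )
    for chrom, common in shared_sites(methylomes).items():
        mask = np.ones(len(common), dtype=bool)
        for m, imap in zip(methylomes, index_maps):
            s = m.chroms[chrom]
            idx = np.array([imap[chrom][int(p)] for p in common], dtype=np.int64)
            mask &= s.coverage[idx] >= min_coverage
        eligible.extend((chrom, int(p)) for p in common[mask])
    if not eligible:
        raise ValidationError("no CpG is covered in all samples at the required depth")
    rng = np.random.default_rng(seed)
    if n < len(eligible):
        pick = rng.choice(len(eligible), size=n, replace=False)
        chosen = [eligible[i] for i in sorted(pick)]
    else:
        chosen = eligible
    matrix = np.empty((len(chosen), len(methylomes)))
    for j, (m, imap) in enumerate(zip(methylomes, index_maps)):
        for i, (chrom, p) in enumerate(chosen):
            s = m.chroms[chrom]
            k = imap[chrom][p]
            if use_smoothed:
                matrix[i, j] = s.smoothed[k]
            else:
                matrix[i, j] = s.n_meth[k] / max(int(s.coverage[k]), 1)
    return matrix, chosen, [m.sample_id for m in methylomes]


@dataclass
class PCAResult:
    coordinates: np.ndarray        # samples x k
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    sample_ids: List[str]


def pca_samples(
    matrix: np.ndarray, sample_ids: Sequence[str], k: Optional[int] = None
) -> PCAResult:
    """PCA of samples over sampled-CpG scores (samples are observations).

    Components are ordered by decreasing variance; each component's sign is
    fixed so its largest-magnitude loading is positive.
    """
    n_samples = matrix.shape[1]
    if n_samples < 2:
        raise ValidationError("PCA needs at least two samples")
    X = matrix.T  # samples x features
    if k is None:
        k = min(n_samples, matrix.shape[0])
    pca = PCA(n_components=min(k, n_samples, matrix.shape[0]), svd_solver="full")
    coords = pca.fit_transform(X)
    for c in range(coords.shape[1]):
        loading = pca.components_[c]
        if loading[np.argmax(np.abs(loading))] < 0:
            pca.components_[c] = -loading
            coords[:, c] = -coords[:, c]
    return PCAResult(
        coords, pca.explained_variance_, pca.explained_variance_ratio_, list(sample_ids)
    )


def feature_methylation_distribution(
    matrix: np.ndarray,
    sample_ids: Sequence[str],
    site_features: Sequence[set],
) -> Dict[Tuple[str, str], np.ndarray]:
    """Group sampled-CpG scores by genomic feature, per sample.

    ``site_features[i]`` is the set of feature labels of row ``i`` (a CpG in
    both an exon and a 5' UTR contributes to both). Returns the raw score
    multiset per ``(sample_id, feature)``; summarize with
    :func:`decile_summary`.
    """
    if len(site_features) != matrix.shape[0]:
        raise ValueError("site_features must align with matrix rows")
    out: Dict[Tuple[str, str], List[float]] = {}
    for i, feats in enumerate(site_features):
        for j, sid in enumerate(sample_ids):
            for feat in feats:
                out.setdefault((sid, feat), []).append(float(matrix[i, j]))
    return {key: np.array(v) for key, v in out.items()}


def decile_summary(values: np.ndarray) -> np.ndarray:
    """The 0th..100th percentiles in decile steps (11 values)."""
    return np.quantile(values, np.linspace(0, 1, 11))
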