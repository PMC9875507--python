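"""Shuffle-based enrichment of a region set across genomic features.

The observed per-feature region counts are compared with counts obtained
after placing regions of the same number and sizes uniformly at random across
the whole genome (default 20 shuffles, the convention for this analysis).
Enrichment is reported as ``log2((obs + 0.5) / (mean_shuffled + 0.5))``
together with an empirical z score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

from .core import GenomicInterval, ValidationError
from . import intervalops
from .annotation import FEATURES, FeatureMap, annotate_regions, feature_count_table

PSEUDOCOUNT = 0.5
DEFAULT_N_ITERATIONS = 20
MAX_REJECTION_TRIES = 1000


@dataclass(frozen=True)
class EnrichmentResult:
    feature: str
    observed_count: int
    shuffled_counts: tuple
    log2_enrichment: float
    empirical_z: float

    @property
    def mean_shuffled(self) -> float:
        return float(np.mean(self.shuffled_counts))


def shuffle_regions(
    regions: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    exclude: Optional[Sequence[GenomicInterval]] = None,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> List[GenomicInterval]:
    """Place regions of identical sizes uniformly at random genome-wide.

    For each region a chromosome is drawn with probability proportional to
    its placeable length (``size - len + 1``) and a start uniform on the
    placeable range; placements intersecting ``exclude`` are rejected and
    resampled (up to 1000 tries). Shuffled regions may overlap one another.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    excl = intervalops.by_chrom(intervalops.merge(exclude)) if exclude else {}
    out: List[GenomicInterval] = []
    for region in regions:
        length = len(region)
        placeable = np.maximum(sizes - length + 1, 0)
        if placeable.sum() == 0:
            raise ValidationError(
                f"region of length {length} does not fit on any chromosome"
            )
        probs = placeable / placeable.sum()
        for _ in range(MAX_REJECTION_TRIES):
            ci = int(rng.choice(len(chroms), p=probs))
            start = int(rng.integers(0, placeable[ci]))
            candidate = GenomicInterval(chroms[ci], start, start + length)
            hits = excl.get(candidate.chrom, [])
            if any(iv.overlaps(candidate) for _, iv in hits):
                continue
            out.append(candidate)
            break
        else:
            raise ValidationError(
                f"could not place region {region.chrom}:{region.start}-{region.end} "
                f"outside the excluded set in {MAX_REJECTION_TRIES} tries"
            )
    return out


def feature_enrichment(
    regions: Sequence[GenomicInterval],
    fmap: FeatureMap,
    n_iterations: int = DEFAULT_N_ITERATIONS,
    seed: int = 0,
    exclude: Optional[Sequence[GenomicInterval]] = None,
) -> List[EnrichmentResult]:
    """Observed vs shuffled per-feature counts for a region set.

    Counting follows the annotation rule: a region counts once in every
    feature it overlaps. The empirical z is ``(obs - mean) / sd`` over the
    shuffled counts (0 when the shuffled counts are constant).
    """
    if not regions:
        raise ValidationError("enrichment needs a non-empty region set")
    if n_iterations < 2:
        raise ValidationError("need at least 2 shuffle iterations")
    observed = feature_count_table(annotate_regions(regions, fmap))
    rng = np.random.default_rng(seed)
    shuffled: Dict[str, List[int]] = {f: [] for f in FEATURES}
    for _ in range(n_iterations):
        placed = shuffle_regions(regions, fmap.chrom_sizes, exclude, rng=rng)
        counts = feature_count_table(annotate_regions(placed, fmap))
        for f in FEATURES:
            shuffled[f].append(counts[f])
    out = []
    for f in FEATURES:
        sh = np.array(shuffled[f], dtype=float)
        log2_enr = float(
            np.log2((observed[f] + PSEUDOCOUNT) / (sh.mean() + PSEUDOCOUNT))
        )
        sd = sh.std(ddof=1)
        z = float((observed[f] - sh.mean()) / sd) if sd > 0 else 0.0
        out.append(
            EnrichmentResult(f, observed[f], tuple(int(x) for x in sh), log2_enr, z)
        )
    return out
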