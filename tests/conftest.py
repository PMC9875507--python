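"""Shared fixtures: one synthetic study per session, plus brute-force oracles."""

import numpy as np
import pytest

from methylscape.core import GenomicInterval
from methylscape.synthetic import CONDITIONS, generate_study

STUDY_SEED = 7


@pytest.fixture(scope="session")
def study():
    """The default synthetic study (4 conditions x 3 replicates)."""
    return generate_study(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def fmap(study):
    return study.feature_map()


@pytest.fixture(scope="session")
def all_methylomes(study):
    return [m for cond in CONDITIONS for m in study.methylomes[cond]]


def random_intervals(rng, n, n_chroms=3, chrom_size=100_000, max_len=2_000):
    """Random interval fixture used across oracle tests."""
    out = []
    for _ in range(n):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, chrom_size - max_len))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def brute_force_overlap_pairs(a, b):
    """Quadratic oracle for interval overlap enumeration."""
    return sorted(
        (i, j)
        for i, x in enumerate(a)
        for j, y in enumerate(b)
        if x.chrom == y.chrom and x.start < y.end and y.start < x.end
    )


def brute_force_covered_bp(intervals, chrom, start, end):
    """Oracle: bp of [start, end) on chrom covered by >= 1 interval."""
    mask = np.zeros(end - start, dtype=bool)
    for iv in intervals:
        if iv.chrom != chrom:
            continue
        s, e = max(iv.start, start), min(iv.end, end)
        if s < e:
            mask[s - start : e - start] = True
    return int(mask.sum())
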