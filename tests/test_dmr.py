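"""DMR statistics and calling: formula oracle, sign conventions, path logic."""

import numpy as np
import pytest

from methylscape.core import GenomicInterval, ValidationError
from methylscape.dmr import DMR, call_dmrs, dmr_paths, per_cpg_t_statistic
from methylscape.methylome import smooth_methylome

from test_methylome import make_methylome


def _replicates(pos, mu, cov, rng, n=3, label="g"):
    out = []
    for r in range(n):
        c = np.full(len(pos), cov)
        k = rng.binomial(c, np.clip(mu + rng.normal(0, 0.01, len(pos)), 0.001, 0.999))
        m = make_methylome(pos, k, c - k, sample_id=f"{label}{r}")
        smooth_methylome(m, 500, 10)
        out.append(m)
    return out


class TestTStatistic:
    def test_identical_groups_give_zero(self):
        pos = np.arange(0, 5000, 50)
        rng = np.random.default_rng(1)
        cov = np.full(len(pos), 20)
        k = rng.binomial(cov, 0.5)
        group = []
        for r in range(3):
            m = make_methylome(pos, k, cov - k, sample_id=f"s{r}")
            smooth_methylome(m, 500, 10)
            group.append(m)
        ts = per_cpg_t_statistic(group, group)
        assert np.allclose(ts.all_t(), 0.0)

    def test_swapping_groups_negates_t(self):
        pos = np.arange(0, 5000, 50)
        rng = np.random.default_rng(2)
        a = _replicates(pos, np.full(len(pos), 0.7), 20, rng, label="a")
        b = _replicates(pos, np.full(len(pos), 0.3), 20, rng, label="b")
        t_ab = per_cpg_t_statistic(a, b)
        t_ba = per_cpg_t_statistic(b, a)
        assert np.allclose(t_ab.all_t(), -t_ba.all_t())

    def test_matches_independent_formula_oracle(self):
        """Direct re-derivation of the statistic at every site of a 3v3 fixture."""
        pos = np.arange(0, 10_000, 100)  # 100 CpGs
        rng = np.random.default_rng(3)
        mu = rng.uniform(0.2, 0.8, len(pos))
        a = _replicates(pos, mu, 20, rng, label="a")
        b = _replicates(pos, np.clip(mu + 0.1, 0, 1), 20, rng, label="b")
        ts = per_cpg_t_statistic(a, b, min_coverage=1)
        got = ts.chroms["chr1"]

        sm_a = np.column_stack([m.chroms["chr1"].smoothed for m in a])
        sm_b = np.column_stack([m.chroms["chr1"].smoothed for m in b])
        keep = np.isin(pos, got["pos"])
        sm_a, sm_b = sm_a[keep], sm_b[keep]
        p = pos[keep]
        diff = sm_b.mean(1) - sm_a.mean(1)
        pooled = np.sqrt((sm_a.std(1, ddof=1) ** 2 + sm_b.std(1, ddof=1) ** 2) / 2)
        local = np.array(
            [pooled[(p >= x - 500) & (p <= x + 500)].mean() for x in p]
        )
        floor = np.quantile(local, 0.75)
        expected = diff / np.maximum(local, floor)
        assert np.allclose(got["t"], expected, atol=1e-10)

    def test_requires_two_replicates_per_group(self):
        pos = np.arange(0, 1000, 50)
        m = make_methylome(pos, np.full(len(pos), 5), np.full(len(pos), 5))
        smooth_methylome(m, 500, 5)
        with pytest.raises(ValidationError):
            per_cpg_t_statistic([m], [m, m])


class TestCallDmrs:
    def _planted_pair(self, delta, seed=4):
        rng = np.random.default_rng(seed)
        pos = np.sort(rng.choice(200_000, size=4000, replace=False))
        mu_a = np.full(len(pos), 0.6)
        mu_b = mu_a.copy()
        block = slice(2000, 2020)  # 20-CpG block
        mu_b[block] = np.clip(mu_a[block] + delta, 0.01, 0.99)
        a = _replicates(pos, mu_a, 30, rng, label="a")
        b = _replicates(pos, mu_b, 30, rng, label="b")
        return pos, block, per_cpg_t_statistic(a, b, min_coverage=4)

    def test_single_planted_block_recovered_as_hyper(self):
        pos, block, ts = self._planted_pair(+0.5)
        dmrs = call_dmrs(ts, "test")
        assert len(dmrs) >= 1
        best = max(dmrs, key=lambda d: abs(d.area_stat))
        assert best.direction == "hyper"
        span = GenomicInterval("chr1", int(pos[block][0]), int(pos[block][-1]) + 1)
        ov = min(best.interval.end, span.end) - max(best.interval.start, span.start)
        assert ov >= 0.8 * len(span)

    def test_negative_delta_called_hypo(self):
        _, _, ts = self._planted_pair(-0.5)
        dmrs = call_dmrs(ts, "test")
        best = max(dmrs, key=lambda d: abs(d.area_stat))
        assert best.direction == "hypo" and best.mean_diff < 0

    def test_degenerate_t_distribution_yields_no_dmrs(self):
        ts_chroms = {"chr1": {"pos": np.arange(10) * 100,
                              "t": np.zeros(10), "mean_diff": np.zeros(10)}}
        from methylscape.dmr import TStatistics

        with pytest.warns(UserWarning):
            assert call_dmrs(TStatistics(ts_chroms, 0.1)) == []

    def test_direction_must_match_sign(self):
        with pytest.raises(ValidationError):
            DMR(GenomicInterval("chr1", 0, 10), "p", "hyper", 5, -0.3, -1.0)


class TestPaths:
    def _groups(self, seed=5):
        rng = np.random.default_rng(seed)
        pos = np.sort(rng.choice(100_000, size=2000, replace=False))
        # plant changes on the fiber lineage only: a region losing methylation
        # at both steps epi(E14.5)->fib(E14.5)->fib(P0.5)
        block = slice(1000, 1030)
        mu = {}
        base = np.full(len(pos), 0.7)
        mu[("epithelium", "E14.5")] = base.copy()
        mu[("epithelium", "P0.5")] = base.copy()
        fe = base.copy()
        fe[block] = 0.4
        mu[("fiber", "E14.5")] = fe
        fp = base.copy()
        fp[block] = 0.1
        mu[("fiber", "P0.5")] = fp
        groups = {
            cond: _replicates(pos, mu[cond], 30, rng, label=str(cond))
            for cond in mu
        }
        return pos, block, groups

    def test_unchanged_path_has_no_strong_calls(self):
        pos, block, groups = self._groups()
        sets = dmr_paths(groups)
        region = GenomicInterval("chr1", int(pos[block][0]), int(pos[block][-1]) + 1)

        def hits(dmrs):
            return [d for d in dmrs if d.interval.overlaps(region)]

        assert not hits(sets["Epi(dif)"])
        assert any(d.direction == "hypo" for d in hits(sets["EpiFiber(dif)"]))
        assert any(d.direction == "hypo" for d in hits(sets["Fiber(dif)"]))

    def test_unidirectional_change_appears_in_direct_contrast(self):
        pos, block, groups = self._groups()
        sets = dmr_paths(groups)
        region = GenomicInterval("chr1", int(pos[block][0]), int(pos[block][-1]) + 1)
        direct = sets["Epi(E14.5)->Fiber(P0.5)"]
        assert any(
            d.direction == "hypo" and d.interval.overlaps(region) for d in direct
        )

    def test_missing_condition_is_named(self):
        pos = np.arange(0, 1000, 50)
        rng = np.random.default_rng(6)
        groups = {("epithelium", "E14.5"): _replicates(pos, np.full(len(pos), 0.5), 20, rng)}
        with pytest.raises(ValidationError, match="P0.5"):
            dmr_paths(groups)

    def test_orientation_early_high_advanced_low_is_hypo(self):
        rng = np.random.default_rng(7)
        pos = np.sort(rng.choice(100_000, size=2000, replace=False))
        block = slice(900, 930)
        hi = np.full(len(pos), 0.8)
        lo = hi.copy()
        lo[block] = 0.2
        groups = {
            ("epithelium", "E14.5"): _replicates(pos, hi, 30, rng, label="e14"),
            ("epithelium", "P0.5"): _replicates(pos, lo, 30, rng, label="p05"),
            ("fiber", "E14.5"): _replicates(pos, hi, 30, rng, label="f14"),
            ("fiber", "P0.5"): _replicates(pos, hi, 30, rng, label="f05"),
        }
        sets = dmr_paths(groups)
        region = GenomicInterval("chr1", int(pos[block][0]), int(pos[block][-1]) + 1)
        epi_hits = [d for d in sets["Epi(dif)"] if d.interval.overlaps(region)]
        assert epi_hits and all(d.direction == "hypo" for d in epi_hits)

    def test_reversing_labels_swaps_hyper_and_hypo(self):
        rng = np.random.default_rng(8)
        pos = np.sort(rng.choice(100_000, size=2000, replace=False))
        mu_a = np.full(len(pos), 0.6)
        mu_b = mu_a.copy()
        mu_b[500:530] = 0.2
        a = _replicates(pos, mu_a, 30, rng, label="a")
        b = _replicates(pos, mu_b, 30, rng, label="b")
        fwd = call_dmrs(per_cpg_t_statistic(a, b), "f")
        rev = call_dmrs(per_cpg_t_statistic(b, a), "r")
        assert [(d.interval, d.direction) for d in fwd] == [
            (d.interval, {"hyper": "hypo", "hypo": "hyper"}[d.direction]) for d in rev
        ]
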