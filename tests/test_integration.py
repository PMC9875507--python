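"""Peak/DMR/DAR/DEG cross-analyses: oracles, partitions, planted designs."""

import numpy as np
import pytest

from methylscape.core import GenomicInterval, ValidationError
from methylscape import intervalops
from methylscape.annotation import build_feature_map
from methylscape.dmr import DMR
from methylscape.io import DEGRecord
from methylscape.integration import (
    assign_state,
    associate_dmars_degs,
    call_dmars,
    chromatin_states,
    classify_peak_specificity,
    classify_tf_peaks_by_chromatin,
    crosstab_dmrs_by_state,
    intersect_sets,
    merge_replicate_peaks,
    peak_umr_lmr_crosstab,
)
from methylscape.segmentation import MethylRegion

from conftest import brute_force_overlap_pairs, random_intervals
from test_annotation import SIZES, simple_gene


def dmr(chrom, start, end, direction="hypo", path="p"):
    diff = 0.3 if direction == "hyper" else -0.3
    return DMR(GenomicInterval(chrom, start, end), path, direction, 5, diff, diff * 10)


class TestIntersect:
    def test_adjacent_half_open_intervals_do_not_overlap(self):
        assert intersect_sets(
            [GenomicInterval("chr1", 0, 10)], [GenomicInterval("chr1", 10, 20)]
        ) == []

    def test_partial_overlap_piece(self):
        pieces = intersect_sets(
            [GenomicInterval("chr1", 0, 10)],
            [GenomicInterval("chr1", 5, 20)],
            mode="intersection_pieces",
        )
        assert pieces == [GenomicInterval("chr1", 5, 10)]

    @pytest.mark.parametrize("seed", range(3))
    def test_pairs_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_intervals(rng, 150), random_intervals(rng, 150)
        assert intersect_sets(a, b) == brute_force_overlap_pairs(a, b)


class TestPeakSpecificity:
    def test_identical_sets_all_shared(self):
        peaks = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 500, 700)]
        out = classify_peak_specificity(peaks, peaks)
        assert {p.specificity for p in out} == {"shared"}

    def test_disjoint_sets_have_no_shared(self):
        epi = [GenomicInterval("chr1", 0, 100)]
        fib = [GenomicInterval("chr1", 500, 700)]
        out = classify_peak_specificity(epi, fib)
        assert sorted(p.specificity for p in out) == ["epithelium_specific", "fiber_specific"]

    def test_planted_shared_fraction_recovered(self):
        rng = np.random.default_rng(41)
        epi, fib = [], []
        n = 1000
        for i in range(n):
            start = 1000 * i
            if i % 10 < 3:  # 30% shared: same locus in both compartments
                epi.append(GenomicInterval("chr1", start, start + 400))
                fib.append(GenomicInterval("chr1", start + 100, start + 500))
            elif i % 10 < 7:
                epi.append(GenomicInterval("chr1", start, start + 300))
            else:
                fib.append(GenomicInterval("chr1", start, start + 300))
        out = classify_peak_specificity(epi, fib)
        shared = sum(1 for p in out if p.specificity == "shared")
        assert shared / n == pytest.approx(0.30, abs=0.02)

    def test_replicate_merge_keeps_bp_supported_by_both(self):
        r1 = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 200, 300)]
        r2 = [GenomicInterval("chr1", 50, 250)]
        assert merge_replicate_peaks(r1, r2) == [
            GenomicInterval("chr1", 50, 100),
            GenomicInterval("chr1", 200, 250),
        ]


class TestChromatinStates:
    def test_no_dars_identical_peaks(self):
        peaks = [GenomicInterval("chr1", 100, 300)]
        st = chromatin_states(peaks, peaks, {}, {"chr1": 1000})
        assert st["stable_open"] == peaks
        assert st["stable_closed"] == [
            GenomicInterval("chr1", 0, 100),
            GenomicInterval("chr1", 300, 1000),
        ]
        assert st["opening"] == [] and st["closing"] == []

    def test_dar_excised_from_stable_open(self):
        peaks = [GenomicInterval("chr1", 100, 500)]
        dars = {"opening": [GenomicInterval("chr1", 200, 300)]}
        st = chromatin_states(peaks, peaks, dars, {"chr1": 1000})
        assert st["stable_open"] == [
            GenomicInterval("chr1", 100, 200),
            GenomicInterval("chr1", 300, 500),
        ]

    def test_overlapping_opening_closing_rejected(self):
        dars = {
            "opening": [GenomicInterval("chr1", 0, 100)],
            "closing": [GenomicInterval("chr1", 50, 150)],
        }
        with pytest.raises(ValidationError):
            chromatin_states([], [], dars, {"chr1": 1000})

    @pytest.mark.parametrize("seed", range(5))
    def test_states_partition_genome_exactly(self, seed):
        rng = np.random.default_rng(seed)
        sizes = {"chr1": 100_000, "chr2": 80_000}
        pa = random_intervals(rng, 40, n_chroms=2, chrom_size=80_000)
        pb = random_intervals(rng, 40, n_chroms=2, chrom_size=80_000)
        opening = random_intervals(rng, 10, n_chroms=2, chrom_size=80_000, max_len=400)
        closing = []
        occupied = intervalops.merge(opening)
        for iv in random_intervals(rng, 30, n_chroms=2, chrom_size=80_000, max_len=400):
            if not any(iv.overlaps(o) for o in occupied):
                closing.append(iv)
                occupied = intervalops.merge(occupied + [iv])
        st = chromatin_states(pa, pb, {"opening": opening, "closing": closing}, sizes)
        total = sum(intervalops.total_bp(v) for v in st.values())
        assert total == sum(sizes.values())
        for s1 in st:
            for s2 in st:
                if s1 < s2:
                    assert not intervalops.intersect_pieces(st[s1], st[s2])


class TestCrosstab:
    def _states(self):
        return {
            "opening": [GenomicInterval("chr1", 0, 1000)],
            "closing": [GenomicInterval("chr1", 1000, 2000)],
            "stable_open": [GenomicInterval("chr1", 2000, 3000)],
            "stable_closed": [GenomicInterval("chr1", 3000, 100_000)],
        }

    def test_majority_bp_assignment(self):
        st = self._states()
        assert assign_state(GenomicInterval("chr1", 400, 1000), st) == "opening"
        assert assign_state(GenomicInterval("chr1", 600, 1600), st) == "closing"
        assert assign_state(GenomicInterval("chr1", 5000, 6000), st) == "stable_closed"

    def test_tie_breaks_follow_fixed_order(self):
        st = self._states()
        # 500 bp in opening, 500 bp in closing -> opening wins
        assert assign_state(GenomicInterval("chr1", 500, 1500), st) == "opening"

    def test_marginals_conserve_feature_incidences(self):
        fmap = build_feature_map([simple_gene("+", 10_000)], SIZES)
        st = self._states()
        dmrs = [
            dmr("chr1", 500, 1500),
            dmr("chr1", 9_500, 10_500, "hyper"),
            dmr("chr1", 50_000, 50_100),
        ]
        table = crosstab_dmrs_by_state(dmrs, st, fmap)
        from methylscape.annotation import annotate_regions

        annos = annotate_regions([d.interval for d in dmrs], fmap)
        assert table["count"].sum() == sum(len(a.features) for a in annos)


class TestDmars:
    def test_hypo_opening_pair(self):
        dmrs = [dmr("chr1", 100, 300, "hypo")]
        dars = {"opening": [GenomicInterval("chr1", 200, 400)]}
        (x,) = call_dmars(dmrs, dars)
        assert x.dar_direction == "opening" and x.dmr.direction == "hypo"
        assert (x.region.start, x.region.end) == (200, 300)

    def test_no_overlap_no_dmars(self):
        dmrs = [dmr("chr1", 100, 300)]
        dars = {"opening": [GenomicInterval("chr1", 500, 600)]}
        assert call_dmars(dmrs, dars) == []

    @pytest.mark.parametrize("seed", range(3))
    def test_pair_count_matches_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        dmrs = [
            dmr(iv.chrom, iv.start, iv.end) for iv in random_intervals(rng, 100)
        ]
        opening = random_intervals(rng, 60)
        closing = random_intervals(rng, 60)
        got = call_dmars(dmrs, {"opening": opening, "closing": closing})
        expected = len(
            brute_force_overlap_pairs([d.interval for d in dmrs], opening)
        ) + len(brute_force_overlap_pairs([d.interval for d in dmrs], closing))
        assert len(got) == expected


class TestDegAssociation:
    def _fmap(self):
        return build_feature_map([simple_gene("+", 10_000)], SIZES)

    def test_promoter_dmar_of_up_gene_labeled_up(self):
        fmap = self._fmap()
        dmrs = [dmr("chr1", 9_200, 9_900)]
        dars = {"opening": [GenomicInterval("chr1", 9_000, 10_000)]}
        dmars = call_dmars(dmrs, dars, fmap)
        labeled, per_dmar, per_deg = associate_dmars_degs(
            dmars, [DEGRecord("g1", 2.0, 1e-4, "up")]
        )
        assert labeled[0].deg_direction == "up"
        assert per_dmar["count"].sum() == 1

    def test_intergenic_dmar_has_no_gene(self):
        fmap = self._fmap()
        dmrs = [dmr("chr1", 50_000, 50_200)]
        dars = {"opening": [GenomicInterval("chr1", 50_000, 50_300)]}
        labeled, _, _ = associate_dmars_degs(call_dmars(dmrs, dars, fmap), [])
        assert labeled[0].deg_direction == "no_gene"

    def test_gene_present_but_not_significant_is_none(self):
        fmap = self._fmap()
        dmrs = [dmr("chr1", 9_200, 9_900)]
        dars = {"opening": [GenomicInterval("chr1", 9_000, 10_000)]}
        labeled, _, _ = associate_dmars_degs(
            call_dmars(dmrs, dars, fmap), [DEGRecord("g1", 0.2, 0.8, "none")]
        )
        assert labeled[0].deg_direction == "none"

    def test_id_space_mismatch_detected(self):
        fmap = self._fmap()
        dmrs = [dmr("chr1", 9_200, 9_900)]
        dars = {"opening": [GenomicInterval("chr1", 9_000, 10_000)]}
        dmars = call_dmars(dmrs, dars, fmap)
        with pytest.raises(ValidationError, match="identifier"):
            associate_dmars_degs(dmars, [DEGRecord("ENSMUSG000001", 1.0, 0.01, "up")])


class TestTfPeaks:
    def test_partition_against_atac(self):
        atac = [GenomicInterval("chr1", 1000, 2000)]
        peaks = [
            GenomicInterval("chr1", 1200, 1400),  # inside open chromatin
            GenomicInterval("chr1", 5000, 5200),  # desert
        ]
        out = classify_tf_peaks_by_chromatin(peaks, atac)
        assert out["open_associated"] == [peaks[0]]
        assert out["closed_associated"] == [peaks[1]]
        assert len(out["open_associated"]) + len(out["closed_associated"]) == len(peaks)


class TestPeakUmrLmrCrosstab:
    def test_rows_partition_peaks(self):
        fmap = build_feature_map([simple_gene("+", 10_000)], SIZES)
        epi = [MethylRegion(GenomicInterval("chr1", 9_000, 9_500), 40, 0.1, "UMR")]
        fib = [
            MethylRegion(GenomicInterval("chr1", 9_000, 9_500), 40, 0.1, "UMR"),
            MethylRegion(GenomicInterval("chr1", 30_000, 30_500), 12, 0.35, "LMR"),
        ]
        peaks = [
            GenomicInterval("chr1", 9_100, 9_300),   # shared
            GenomicInterval("chr1", 30_100, 30_200),  # fiber only
            GenomicInterval("chr1", 70_000, 70_200),  # none
        ]
        df = peak_umr_lmr_crosstab(peaks, {"epithelium": epi, "fiber": fib}, fmap)
        assert df.loc["shared", "n_peaks"] == 1
        assert df.loc["fiber", "n_peaks"] == 1
        assert df.loc["no_umr_lmr", "n_peaks"] == 1
        assert df["n_peaks"].sum() == len(peaks)
        assert df.loc["shared", "proximal_promoter"] == 1
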