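"""Unit and property tests for the windowed Fst / theta-pi sweep scan."""

import math

import numpy as np
import pandas as pd
import pytest

from medsweep import io as msio
from medsweep.popgen import (
    GenotypeMatrix,
    PopulationSplit,
    SweepRegions,
    Window,
    call_sweep_regions,
    genes_in_regions,
    log2_pi_ratio,
    make_windows,
    merge_intervals,
    read_vcf_biallelic,
    select_top_fraction,
    site_pi,
    wc_components_matrix,
    wc_site_components,
    window_fst,
    window_pi,
    window_scan,
)

from .conftest import make_gm, random_site_pair
from .oracles import brute_site_pi, brute_wc_site, brute_windowed_fst


class TestReadVcf:
    def test_filters_to_biallelic_snps(self, toy_vcf):
        gm = read_vcf_biallelic(toy_vcf)
        assert gm.n_sites == 3
        assert list(gm.pos) == [100, 200, 500]

    def test_gt_semantics(self, toy_vcf):
        gm = read_vcf_biallelic(toy_vcf)
        # site 100: 0/0, 0/1, 1|1 ; site 200 has one missing call
        assert gm.dosages[0].tolist() == [0, 1, 2]
        assert gm.dosages[1].tolist() == [0, -1, 1]

    def test_min_call_rate_drops_sites_with_missing(self, toy_vcf):
        gm = read_vcf_biallelic(toy_vcf, min_call_rate=1.0)
        assert list(gm.pos) == [100, 500]


class TestMakeWindows:
    @pytest.mark.parametrize(
        "length,n_expected,last",
        [
            (100_000, 5, (80_000, 100_000, True)),
            (40_000, 2, (20_000, 40_000, True)),
            (10_000, 1, (0, 10_000, True)),
        ],
    )
    def test_window_grid(self, length, n_expected, last):
        wins = make_windows({"chr1": length})
        assert len(wins) == n_expected
        w = wins[-1]
        assert (w.start, w.end, w.truncated) == last

    def test_full_windows_not_flagged(self):
        wins = make_windows({"chr1": 100_000})
        assert not wins[0].truncated and wins[0].end - wins[0].start == 40_000

    def test_step_larger_than_size_rejected(self):
        with pytest.raises(ValueError):
            make_windows({"chr1": 100_000}, size=10_000, step=20_000)


class TestSitePi:
    def test_two_by_two_alleles(self):
        # {A,A,T,T}: 4 of 6 pairs differ
        assert site_pi(2, 2) == pytest.approx(2 / 3)
        assert site_pi(2, 2) == pytest.approx(brute_site_pi([0, 0, 1, 1]))

    def test_monomorphic_is_zero(self):
        assert site_pi(4, 0) == 0.0

    def test_single_pair(self):
        assert site_pi(1, 1) == 1.0

    def test_too_few_alleles_rejected(self):
        with pytest.raises(ValueError):
            site_pi(1, 0)

    def test_matches_brute_enumeration_randomly(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            rc, ac = int(rng.integers(0, 8)), int(rng.integers(0, 8))
            if rc + ac < 2:
                continue
            alleles = [0] * rc + [1] * ac
            assert site_pi(rc, ac) == pytest.approx(brute_site_pi(alleles), abs=1e-15)


class TestWeirCockerham:
    def test_fixed_difference_gives_theta_one(self):
        d = np.array([[0] * 5 + [2] * 5])
        a, b, c, _ = wc_components_matrix(d, np.arange(5), np.arange(5, 10))
        assert (a[0], b[0], c[0]) == (0.5, 0.0, 0.0)
        assert window_fst(a, b, c) == 1.0

    def test_identical_heterozygotes_give_theta_zero(self):
        d = np.array([[1, 1, 1, 1]])
        a, b, c, _ = wc_components_matrix(d, np.arange(2), np.arange(2, 4))
        assert a[0] == pytest.approx(0.0)
        assert b[0] == pytest.approx(-0.25)
        assert c[0] == pytest.approx(0.5)
        assert window_fst(a, b, c) == 0.0

    def test_monomorphic_site_contributes_nothing(self):
        d = np.array([[0, 0, 0, 0, 0, 0, 0, 0]])
        a, b, c, _ = wc_components_matrix(d, np.arange(4), np.arange(4, 8))
        assert a[0] == b[0] == c[0] == 0.0

    def test_underpopulated_site_skipped(self):
        row = np.array([1, -1, -1, 0, 1, 2])
        assert wc_site_components(row, np.arange(3), np.arange(3, 6)) is None

    def test_matches_brute_force_on_random_sites(self):
        """Two-route check against the scalar-loop W&C oracle."""
        rng = np.random.default_rng(42)
        for _ in range(500):
            pop1, pop2 = random_site_pair(rng)
            row = np.array(pop1 + pop2, dtype=np.int8)
            got = wc_site_components(
                row, np.arange(len(pop1)), np.arange(len(pop1), len(row))
            )
            expected = brute_wc_site(pop1, pop2)
            assert got is not None and expected is not None
            for g, e in zip(got, expected):
                assert g == pytest.approx(e, abs=1e-12)

    def test_ratio_of_sums_matches_brute_force(self):
        rng = np.random.default_rng(7)
        sites = [random_site_pair(rng) for _ in range(200)]
        rows, idx1_len = [], len(sites[0][0])
        # pad to a rectangular matrix with missing codes
        width1 = max(len(p1) for p1, _ in sites)
        width2 = max(len(p2) for _, p2 in sites)
        mat = np.full((len(sites), width1 + width2), -1, dtype=np.int8)
        for i, (p1, p2) in enumerate(sites):
            mat[i, : len(p1)] = p1
            mat[i, width1 : width1 + len(p2)] = p2
        a, b, c, usable = wc_components_matrix(
            mat, np.arange(width1), np.arange(width1, width1 + width2)
        )
        got = window_fst(a[usable], b[usable], c[usable])
        assert got == pytest.approx(brute_windowed_fst(sites), abs=1e-12)

    def test_label_permutation_within_population_invariant(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, (50, 10)).astype(np.int8)
        idx1, idx2 = np.arange(5), np.arange(5, 10)
        a1, b1, c1, _ = wc_components_matrix(d, idx1, idx2)
        perm = np.array([3, 0, 4, 1, 2])
        a2, b2, c2, _ = wc_components_matrix(d, idx1[perm], idx2[perm[::-1]])
        np.testing.assert_allclose(a1, a2, atol=1e-14)
        np.testing.assert_allclose(b1, b2, atol=1e-14)
        np.testing.assert_allclose(c1, c2, atol=1e-14)


class TestWindowPi:
    def test_empty_window_is_zero(self):
        gm = make_gm([[0, 0, 1, 1]], pos=[50_000])
        mask = np.array([False])
        assert window_pi(gm, np.arange(4), mask, 40_000) == 0.0

    def test_single_site_normalization(self):
        # one site with alleles {A,A,T,T}: pi = 2/3, over a 40 kb window
        gm = make_gm([[0, 2]])
        mask = np.array([True])
        assert window_pi(gm, np.arange(2), mask, 40_000) == pytest.approx(
            (2 / 3) / 40_000
        )

    def test_per_bp_invariance_under_doubling(self):
        rows = [[0, 1, 2, 0], [2, 1, 0, 0]]
        gm1 = make_gm(rows)
        gm2 = make_gm(rows + rows, pos=[100, 200, 300, 400])
        v1 = window_pi(gm1, np.arange(4), np.array([True] * 2), 10_000)
        v2 = window_pi(gm2, np.arange(4), np.array([True] * 4), 20_000)
        assert v1 == pytest.approx(v2)


class TestLog2Ratio:
    def test_value_and_degenerate_policies(self):
        assert log2_pi_ratio(0.002, 0.0005) == pytest.approx(2.0)
        assert log2_pi_ratio(0.001, 0.001) == 0.0
        assert math.isnan(log2_pi_ratio(0.001, 0.0))
        with pytest.raises(ValueError):
            log2_pi_ratio(-0.1, 0.2)


def _stats_frame(values):
    return pd.DataFrame(
        dict(
            chrom=["chr1"] * len(values),
            start=[i * 20_000 for i in range(len(values))],
            end=[i * 20_000 + 40_000 for i in range(len(values))],
            fst=values,
        )
    )


class TestSelectTopFraction:
    def test_rank_arithmetic(self):
        stats = _stats_frame(list(range(1, 101)))
        sel, thr = select_top_fraction(stats, "fst", 0.05)
        assert sorted(sel["fst"]) == [96, 97, 98, 99, 100]
        assert thr == 96

    def test_total_tie_selects_all_with_warning(self):
        stats = _stats_frame([1.0] * 40)
        with pytest.warns(UserWarning):
            sel, _ = select_top_fraction(stats, "fst", 0.05)
        assert len(sel) == 40

    def test_small_n_selects_none(self):
        stats = _stats_frame(list(range(10)))
        with pytest.warns(UserWarning):
            sel, thr = select_top_fraction(stats, "fst", 0.05)
        assert len(sel) == 0 and math.isnan(thr)

    def test_nan_windows_excluded_from_ranking(self):
        stats = _stats_frame([float("nan")] * 10 + list(range(1, 91)))
        sel, _ = select_top_fraction(stats, "fst", 0.05)
        assert len(sel) == 4  # floor(0.05 * 90)


class TestCallSweepRegions:
    def _frame(self, starts):
        return pd.DataFrame(
            dict(
                chrom=["chr1"] * len(starts),
                start=starts,
                end=[s + 40_000 for s in starts],
            )
        )

    def test_intersection_and_merge(self):
        top_f = self._frame([0, 20_000, 40_000])
        top_r = self._frame([20_000, 40_000, 200_000])
        regions = call_sweep_regions(top_f, top_r, "intersection")
        assert regions.intervals == [("chr1", 20_000, 80_000)]

    def test_disjoint_sets_give_empty_regions(self):
        regions = call_sweep_regions(self._frame([0]), self._frame([200_000]))
        assert regions.intervals == []

    def test_union_mode(self):
        regions = call_sweep_regions(
            self._frame([0]), self._frame([200_000]), "union"
        )
        assert len(regions.intervals) == 2

    def test_adjacent_windows_merge(self):
        assert merge_intervals(
            [("chr1", 0, 40_000), ("chr1", 20_000, 60_000)]
        ) == [("chr1", 0, 60_000)]


class TestGenesInRegions:
    def _regions(self, intervals):
        return SweepRegions(intervals=intervals, source_windows=[])

    def test_overlap_and_boundary_convention(self):
        genes = [
            msio.GeneRecord("gA", "chr1", 5_000, 6_000, "+"),
            msio.GeneRecord("gB", "chr1", 40_001, 41_000, "+"),
        ]
        regions = self._regions([("chr1", 0, 40_000)])  # 1-based 1..40000
        assert genes_in_regions(genes, regions) == ["gA"]

    def test_gene_spanning_two_regions_reported_once(self):
        genes = [msio.GeneRecord("gX", "chr1", 30_000, 90_000, "+")]
        regions = self._regions([("chr1", 0, 40_000), ("chr1", 80_000, 120_000)])
        assert genes_in_regions(genes, regions) == ["gX"]


class TestWindowScan:
    def test_min_snps_gates_ranking(self):
        rng = np.random.default_rng(1)
        dos = rng.integers(0, 3, (5, 8)).astype(np.int8)
        gm = make_gm(dos, pos=[100, 200, 300, 400, 500])
        split = PopulationSplit(tuple(gm.sample_ids[:4]), tuple(gm.sample_ids[4:]))
        wins = make_windows({"chr1": 40_000})
        stats = window_scan(gm, split, wins, min_snps=10)
        assert stats["fst"].isna().all()
        stats2 = window_scan(gm, split, wins, min_snps=1)
        assert stats2["fst"].notna().any()
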