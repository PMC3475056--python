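"""Normalization-factor estimators against hand-worked and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ncisnorm.estimators as est_mod
from ncisnorm import (BinTable, ComparatorConfig, DegenerateBackgroundError,
                      GenomeLayout, NcisConfig, background_ratio,
                      ccat_estimate, cisgenome_estimate, ncis_estimate,
                      ncis_fixed_w, peakseq_estimate, pi0_from_r,
                      spp_estimate, synth_background, yeast_like_genome)

from conftest import make_tags


def brute_force_fixed_w(n1, n2, floor=0.75):
    """Independent threshold-search oracle: materialize B_w(t) for every
    distinct total and apply the background ratio directly."""
    n1, n2 = list(n1), list(n2)
    ni = [a + b for a, b in zip(n1, n2)]
    m = len(ni)
    totals = sorted(set(ni))

    def sums(t):
        s1 = sum(a for a, x in zip(n1, ni) if x <= t)
        s2 = sum(b for b, x in zip(n2, ni) if x <= t)
        return s1, s2

    for i in range(1, len(totals)):
        t = totals[i]
        size = sum(1 for x in ni if x <= t)
        if size < floor * m:
            continue
        s1, s2 = sums(t)
        p1, p2 = sums(totals[i - 1])
        if s2 == 0 or p2 == 0:
            continue
        if s1 / s2 >= p1 / p2:
            return s1 / s2, t, size, False
    s1, s2 = sums(totals[-1])
    if s2 == 0:
        raise DegenerateBackgroundError("all-zero control")
    return s1 / s2, totals[-1], m, True


class TestBackgroundRatio:
    def test_direct_sums(self):
        table = BinTable.from_counts([3, 1], [2, 2])
        assert background_ratio(table, np.array([0, 1])) == 1.0

    def test_whole_set_is_retained_totals_ratio(self):
        table = BinTable.from_counts([2, 3, 5], [1, 2, 2])
        assert background_ratio(table, np.arange(3)) == 10 / 5

    def test_zero_control_sum_rejected(self):
        table = BinTable.from_counts([1, 1], [0, 0])
        with pytest.raises(DegenerateBackgroundError):
            background_ratio(table, np.array([0, 1]))

    def test_empty_set_rejected(self):
        table = BinTable.from_counts([1], [1])
        with pytest.raises(DegenerateBackgroundError):
            background_ratio(table, np.array([], dtype=int))


class TestNcisFixedW:
    def test_worked_threshold_search(self):
        # 6x(1,1), 2x(2,1), 1x(1,2), 1x(10,1): eligibility starts at t=3,
        # r(3)=11/10 >= r(2)=1 -> t*=3 on 9 bins
        n1 = [1] * 6 + [2, 2, 1, 10]
        n2 = [1] * 6 + [1, 1, 2, 1]
        r, t, nb, fb = ncis_fixed_w(BinTable.from_counts(n1, n2))
        assert (r, t, nb, fb) == (1.1, 3, 9, False)
        assert brute_force_fixed_w(n1, n2)[:3] == (1.1, 3, 9)

    def test_symmetric_counts_give_unit_ratio(self):
        r, *_ = ncis_fixed_w(BinTable.from_counts([1] * 8, [1] * 8))
        assert r == 1.0

    def test_single_distinct_total_falls_back_to_all_bins(self):
        r, t, nb, fb = ncis_fixed_w(BinTable.from_counts([2, 2], [1, 1]))
        assert fb and r == 2.0 and nb == 2

    def test_all_zero_control_degenerate(self):
        with pytest.raises(DegenerateBackgroundError):
            ncis_fixed_w(BinTable.from_counts([1, 2, 3], [0, 0, 0]))

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 8), st.integers(0, 8))
                    .filter(lambda p: sum(p) > 0),
                    min_size=1, max_size=200))
    def test_matches_brute_force_oracle(self, pairs):
        n1, n2 = zip(*pairs)
        table = BinTable.from_counts(n1, n2)
        try:
            expected = brute_force_fixed_w(n1, n2)
        except DegenerateBackgroundError:
            with pytest.raises(DegenerateBackgroundError):
                ncis_fixed_w(table)
            return
        got = ncis_fixed_w(table)
        assert math.isclose(got.r_hat, expected[0], rel_tol=1e-12)
        assert (got.t_star, got.n_background_bins,
                got.fallback) == expected[1:]


class TestNcisEstimate:
    def test_grid_stop_rule_on_scripted_trace(self, layout, monkeypatch):
        scripted = {100: 1.05, 200: 1.02, 500: 1.03, 1000: 0.9}
        from ncisnorm.estimators import FixedWidthEstimate

        def fake_fixed_w(table, floor):
            return FixedWidthEstimate(scripted[table.w], 1, table.m_w, False)

        monkeypatch.setattr(est_mod, "ncis_fixed_w", fake_fixed_w)
        tags = make_tags("chrA", [10, 500, 900])
        res = est_mod.ncis_estimate(tags, tags, layout)
        assert res.w_star == 200
        assert res.r_hat == 1.02
        assert res.trace == [(100, 1.05), (200, 1.02), (500, 1.03)]

    def test_identity_returns_first_grid_width(self, rng):
        lay = GenomeLayout(("chrA",), (50000,))
        tags = make_tags("chrA", rng.integers(0, 50000, 2000))
        res = ncis_estimate(tags, tags.copy(), lay)
        assert res.r_hat == 1.0
        assert res.pi0_hat == 1.0
        assert res.w_star == 100

    def test_pure_background_recovery(self):
        # equal-depth shared-background pairs: r ~ 1 across replicates
        lay = yeast_like_genome(total_bp=3_000_000, n_chrom=2)
        ss = np.random.SeedSequence(31)
        vals = [ncis_estimate(*synth_background(lay, 50_000, 50_000, seed=s),
                              lay).r_hat for s in ss.spawn(25)]
        assert abs(np.mean(vals) - 1.0) < 0.005

    def test_upper_bound_is_depth_ratio(self):
        # signal only in ChIP: r_hat cannot exceed N1/N2
        lay = yeast_like_genome(total_bp=2_000_000, n_chrom=2)
        from ncisnorm import SimConfig, simulate
        ds = simulate(SimConfig(genome=lay, background_depth=40_000,
                                p=200, seed=5), 1)
        res = ncis_estimate(ds.chip, ds.control, lay)
        assert res.r_hat <= res.depth_ratio

    def test_empty_sample_rejected(self, layout):
        tags = make_tags("chrA", [1])
        with pytest.raises(ValueError):
            ncis_estimate(tags.iloc[0:0], tags, layout)


class TestCisgenome:
    def test_low_count_bins_ratio(self):
        table = BinTable.from_counts([1, 1, 1, 0, 0, 9],
                                     [0, 0, 0, 1, 1, 9])
        res = cisgenome_estimate(table)
        assert res.r_hat == 1.5
        assert res.t_star == 1 and res.n_background_bins == 5

    def test_control_sum_zero_degenerate(self):
        table = BinTable.from_counts([1, 5], [0, 5])
        with pytest.raises(DegenerateBackgroundError):
            cisgenome_estimate(table)

    def test_deeply_sequenced_failure_mode(self):
        # every bin total above t: the fixed threshold is inapplicable
        table = BinTable.from_counts([3, 4], [3, 4])
        with pytest.raises(DegenerateBackgroundError):
            cisgenome_estimate(table)


class TestSpp:
    def _layout_for_rate_one(self, table):
        # rate = N * w / G == 1 when G = N * w
        return GenomeLayout(("chrA",), (int(table.N1) * table.w,))

    def test_no_exclusions_at_modest_counts(self):
        table = BinTable.from_counts([2, 1, 0], [1, 1, 1], w=1000)
        lay = GenomeLayout(("chrA",), (3000,))
        res = spp_estimate(table, lay)
        assert res.r_hat == 3 / 3
        assert res.n_background_bins == 3

    def test_extreme_bin_excluded_per_exact_poisson_tail(self):
        # oracle: exact tail sum P(X >= n) at rate lam
        table = BinTable.from_counts([30, 1, 1], [1, 1, 1], w=1000)
        lay = GenomeLayout(("chrA",), (32 * 1000,))
        lam1 = table.N1 * 1000 / lay.G
        tail = 1.0 - sum(math.exp(-lam1) * lam1 ** k / math.factorial(k)
                         for k in range(30))
        assert tail < 1e-5  # the spiked bin is extreme under uniformity
        res = spp_estimate(table, lay)
        assert res.n_background_bins == 2
        assert res.r_hat == 2 / 2

    def test_zero_count_has_unit_pvalue(self):
        # n=0 bins are never excluded: P(X >= 0) = 1
        table = BinTable.from_counts([0, 1], [0, 1], w=100,
                                     zero_filtered=False)
        lay = GenomeLayout(("chrA",), (200,))
        res = spp_estimate(table, lay)
        assert res.n_background_bins == 2


class TestCcat:
    def test_hand_iterated_example(self):
        # bins A:(+1,2; -2,2), B:(+5,1; -5,1); r0=13/6 -> B={A} -> r=1
        table = BinTable.from_counts([3, 10], [4, 2], w=1000,
                                     n1_plus=[1, 5], n2_plus=[2, 1])
        res = ccat_estimate(table)
        assert res.r_hat == 1.0
        assert "not_converged" not in res.flags

    def test_identity_is_fixed_point(self):
        table = BinTable.from_counts([4, 6], [4, 6],
                                     n1_plus=[2, 3], n2_plus=[2, 3])
        res = ccat_estimate(table)
        assert res.r_hat == 1.0

    def test_zero_iterations_returns_depth_ratio(self):
        table = BinTable.from_counts([3, 10], [4, 2], w=1000,
                                     n1_plus=[1, 5], n2_plus=[2, 1])
        res = ccat_estimate(table, max_iter=0)
        assert res.r_hat == 13 / 6
        assert "not_converged" in res.flags

    def test_degenerate_negative_strand(self):
        # B nonempty but its negative-strand control counts are all zero
        table = BinTable.from_counts([2, 9], [4, 1],
                                     n1_plus=[1, 9], n2_plus=[4, 1])
        with pytest.raises(DegenerateBackgroundError, match="iteration"):
            ccat_estimate(table)


class TestPeakseq:
    def test_exact_linear_slope(self):
        table = BinTable.from_counts([2, 4, 6, 8], [1, 2, 3, 4], w=10000,
                                     zero_filtered=False)
        assert peakseq_estimate(table).r_hat == pytest.approx(2.0)

    def test_identity_slope_one(self):
        table = BinTable.from_counts([1, 2, 3], [1, 2, 3], w=10000,
                                     zero_filtered=False)
        assert peakseq_estimate(table).r_hat == pytest.approx(1.0)

    def test_constant_control_rejected(self):
        table = BinTable.from_counts([1, 2, 3], [2, 2, 2],
                                     zero_filtered=False)
        with pytest.raises(DegenerateBackgroundError):
            peakseq_estimate(table)

    def test_nonzero_exclusion_fraction_unsupported(self):
        table = BinTable.from_counts([1, 2], [1, 2], zero_filtered=False)
        with pytest.raises(NotImplementedError):
            peakseq_estimate(table, pf=0.5)


class TestPi0:
    @pytest.mark.parametrize("r_hat, expected", [
        (1.265, 0.763), (1.370, 0.826)])
    def test_background_proportion_from_depth_ratio(self, r_hat, expected):
        # depth ratio 1.658 as in the deeply sequenced yeast pair
        assert pi0_from_r(r_hat, 1658, 1000) == pytest.approx(expected,
                                                              abs=5e-4)

    def test_depth_ratio_maps_to_one(self):
        assert pi0_from_r(1.658, 1658, 1000) == pytest.approx(1.0)

    def test_above_one_warns_but_returns(self):
        with pytest.warns(UserWarning):
            assert pi0_from_r(2.0, 1000, 1000) == 2.0

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            pi0_from_r(0.0, 10, 10)
        with pytest.raises(ValueError):
            pi0_from_r(1.0, 0, 10)


def test_configs_validated():
    with pytest.raises(ValueError):
        NcisConfig(grid=(100, 100))
    with pytest.raises(ValueError):
        NcisConfig(quartile_floor=1.5)
    with pytest.raises(ValueError):
        ComparatorConfig(spp_c=2.0)


def test_diffuse_domain_recovery():
    """NCIS also recovers the factor when enrichment is spread over
    kilobase-scale domains rather than point sources."""
    from ncisnorm import SimConfig, simulate
    lay = yeast_like_genome(total_bp=6_000_000, n_chrom=3)
    errs = []
    for seed in range(6):
        ds = simulate(SimConfig(genome=lay, background_depth=100_000,
                                c=1.0, p=50, seed=seed), 3)
        r = ncis_estimate(ds.chip, ds.control, lay).r_hat
        errs.append(r - ds.true_r)
    assert abs(np.mean(errs)) < 0.02
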