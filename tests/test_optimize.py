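"""Allocation solvers: analytic anchors, Lagrange conditions, grid oracles."""

import math

import numpy as np
import pytest

from platalloc import (
    DesignError,
    optimize_case1,
    optimize_case2_cc,
    optimize_case2_ncc,
    optimize_case3_cc,
    optimize_case3_ncc,
    optimize_sum_of_variances,
    optimize_unequal_variances,
    var_ncc,
    var_stratified_cc,
)

from _oracles import g, grid_minmax_cc

SQRT2 = math.sqrt(2.0)
SQRT_K = (1 / (1 + SQRT2), 1 - 1 / SQRT2, 1 - 1 / SQRT2)


class TestCase1:
    @pytest.mark.parametrize("mode", ["cc", "ncc"])
    def test_one_period_sqrt_k_allocation(self, mode):
        sol = optimize_case1(mode)
        assert sol.design.r == pytest.approx((0.0, 1.0, 0.0), abs=1e-15)
        assert sol.design.p[1] == pytest.approx(SQRT_K, abs=1e-12)

    def test_objective_is_one_plus_sqrt2_squared(self):
        sol = optimize_case1()
        assert sol.objective == pytest.approx((1 + SQRT2) ** 2, rel=1e-12)
        assert sol.variance_gap == pytest.approx(0.0, abs=1e-12)


class TestCase3Concurrent:
    def test_symmetric_periods_recover_sqrt_k(self):
        sol = optimize_case3_cc(1 / 3, 1 / 3)
        assert sol.scenario == "interior"
        assert sol.design.p[1] == pytest.approx(SQRT_K, abs=1e-10)

    def test_small_head_scenario_drops_arm2(self):
        sol = optimize_case3_cc(0.2, 0.2)
        assert sol.scenario == "r1+r2<1/2"
        assert sol.design.p[1] == pytest.approx((0.5, 0.5, 0.0), abs=1e-15)

    def test_large_r1_scenario_drops_arm1(self):
        sol = optimize_case3_cc(0.6, 0.2)
        assert sol.scenario == "r1>=1/2"
        assert sol.design.p[1] == pytest.approx((0.5, 0.0, 0.5), abs=1e-15)
        # secondary criterion: periods 1 and 3 stay at equal allocation
        assert sol.design.p[0][:2] == pytest.approx((0.5, 0.5), abs=1e-15)
        assert sol.design.p[2][::2] == pytest.approx((0.5, 0.5), abs=1e-15)

    def test_interior_example(self):
        sol = optimize_case3_cc(1 / 3, 4 / 9)
        assert sol.design.p[1] == pytest.approx((0.4248, 0.2010, 0.3742), abs=5e-4)

    def test_interior_solutions_equalize_variances(self):
        for r1, r2 in [(0.1, 0.5), (0.25, 0.5), (1 / 3, 4 / 9), (0.45, 0.4),
                       (0.3, 0.69), (0.05, 0.93)]:
            sol = optimize_case3_cc(r1, r2)
            assert sol.scenario == "interior"
            assert sol.variance_gap < 1e-8 * sol.objective

    def test_interior_stationarity_relation(self):
        # Lagrange conditions: p02^2 = p12^2 + p22^2 at every interior optimum
        for r1, r2 in [(0.1, 0.5), (0.25, 0.6), (1 / 3, 4 / 9), (0.45, 0.35)]:
            p02, p12, p22 = optimize_case3_cc(r1, r2).design.p[1]
            assert p02**2 == pytest.approx(p12**2 + p22**2, abs=1e-8)

    def test_constraint_identity_along_stationarity_curve(self):
        # r2/(1-2*r1) = 1/(4*Delta+1) with Delta = g(p12,p02) - g(p22,p02)
        for r1, r2 in [(0.1, 0.82), (0.25, 0.6), (0.3, 0.5), (0.45, 0.35)]:
            p02, p12, p22 = optimize_case3_cc(r1, r2).design.p[1]
            delta = g(p12, p02) - g(p22, p02)
            assert r2 / (1 - 2 * r1) == pytest.approx(1 / (4 * delta + 1), abs=1e-10)

    def test_matches_grid_search(self):
        for r1, r2 in [(0.25, 0.5), (1 / 3, 4 / 9), (0.3, 0.6)]:
            sol = optimize_case3_cc(r1, r2)
            oracle = grid_minmax_cc(r1, r2)
            assert sol.design.p[1] == pytest.approx(oracle, abs=1e-3)

    def test_monotone_in_r2_with_control_minimum_at_symmetry(self):
        r1 = 0.3
        grid = np.linspace(0.21, 0.69, 17)
        sols = [optimize_case3_cc(r1, r2).design.p[1] for r2 in grid]
        p02, p12, p22 = (np.array(x) for x in zip(*sols))
        assert np.all(np.diff(p22) >= -1e-10)
        assert np.all(np.diff(p12) <= 1e-10)
        k = int(np.argmin(p02))
        assert grid[k] == pytest.approx(1 - 2 * r1, abs=np.diff(grid)[0])

    def test_swapping_r1_r3_swaps_the_arms(self):
        a = optimize_case3_cc(0.25, 0.45).design.p[1]
        b = optimize_case3_cc(0.30, 0.45).design.p[1]  # r3 = 0.25
        assert a[0] == pytest.approx(b[0], abs=1e-12)
        assert a[1] == pytest.approx(b[2], abs=1e-12)
        assert a[2] == pytest.approx(b[1], abs=1e-12)

    def test_rejects_invalid_fractions(self):
        with pytest.raises(DesignError):
            optimize_case3_cc(0.0, 0.5)
        with pytest.raises(DesignError):
            optimize_case3_cc(0.3, 0.8)


class TestCase2Concurrent:
    def test_late_entry_splits_into_separate_trials(self):
        sol = optimize_case2_cc(0.6)
        assert sol.scenario == "r1>=1/2"
        assert sol.design.r == pytest.approx((0.6, 0.0, 0.4), abs=1e-15)
        assert sol.design.p[2][::2] == pytest.approx((0.5, 0.5), abs=1e-15)

    def test_early_entry_keeps_both_arms_to_the_end(self):
        sol = optimize_case2_cc(0.25)
        assert sol.design.r == pytest.approx((0.25, 0.75, 0.0), abs=1e-15)
        assert sol.design.p[1] == pytest.approx((0.4317, 0.1726, 0.3957), abs=5e-4)
        assert sol.variance_gap < 1e-8 * sol.objective

    def test_vanishing_first_period_approaches_one_period_optimum(self):
        sol = optimize_case2_cc(1e-9)
        assert sol.design.p[1] == pytest.approx(SQRT_K, abs=1e-4)


class TestNonConcurrentSolvers:
    def test_boundary_scenarios_match_concurrent_ones(self):
        sol = optimize_case3_ncc(0.55, 0.2)
        assert sol.scenario == "r1>=1/2"
        assert sol.design.p[1] == pytest.approx((0.5, 0.0, 0.5), abs=1e-15)
        sol = optimize_case3_ncc(0.3, 0.1)
        assert sol.scenario == "r1+r2<1/2"
        assert sol.design.p[1] == pytest.approx((0.5, 0.5, 0.0), abs=1e-15)

    def test_interior_equalizes_variances_and_spends_less_control(self):
        for r1, r2 in [(0.25, 0.5), (0.25, 0.75), (0.4, 0.35), (0.15, 0.6)]:
            sol = optimize_case3_ncc(r1, r2)
            assert sol.scenario == "interior"
            assert sol.variance_gap < 1e-8 * sol.objective
            cc = optimize_case3_cc(r1, r2)
            assert sol.design.p[1][0] < cc.design.p[1][0]
            assert sol.objective <= cc.objective * (1 + 1e-9)

    def test_interior_solution_is_feasible_optimum(self):
        # recomputing both variances from the returned design reproduces
        # the reported objective
        sol = optimize_case3_ncc(0.25, 0.5)
        rep = var_ncc(sol.design)
        assert max(rep.var_arm1, rep.var_arm2) == pytest.approx(
            sol.objective, rel=1e-10
        )

    def test_case2_late_entry_two_period_design(self):
        sol = optimize_case2_ncc(0.6)
        assert sol.design.r == pytest.approx((0.6, 0.0, 0.4), abs=1e-15)
        assert sol.scenario == "r1>=1/2"

    def test_case2_interior_beats_concurrent_control_share(self):
        sol = optimize_case2_ncc(0.25)
        assert sol.design.r == pytest.approx((0.25, 0.75, 0.0), abs=1e-15)
        assert sol.variance_gap < 1e-8 * sol.objective
        assert sol.design.p[1][0] < 0.4317

    def test_case2_vanishing_first_period_approaches_one_period_optimum(self):
        sol = optimize_case2_ncc(1e-6)
        assert sol.design.p[1] == pytest.approx(SQRT_K, abs=1e-3)


class TestUnequalVariances:
    def test_equal_sigmas_reduce_to_standard_solver(self):
        sol = optimize_unequal_variances(1 / 3, 1 / 3, (1.0, 1.0, 1.0))
        ref = optimize_case3_cc(1 / 3, 1 / 3)
        assert sol.design.p[1] == pytest.approx(ref.design.p[1], abs=1e-12)

    def test_neyman_allocation_in_single_arm_periods(self):
        sol = optimize_unequal_variances(1 / 3, 1 / 3, (1.0, 2.0, 1.5))
        assert sol.design.p[0][1] == pytest.approx(2 / 3, abs=1e-12)
        assert sol.design.p[0][0] == pytest.approx(1 / 3, abs=1e-12)
        assert sol.design.p[2][2] == pytest.approx(1.5 / 2.5, abs=1e-12)

    def test_noisier_arm_gets_more_patients_in_period2(self):
        sol = optimize_unequal_variances(1 / 3, 1 / 3, (1.0, 1.0, 1.3))
        p02, p12, p22 = sol.design.p[1]
        assert p22 > p12
        assert sol.variance_gap < 1e-6 * sol.objective  # interior here

    def test_matches_dense_grid_oracle(self):
        sigma = (1.0, 1.2, 1.4)
        sol = optimize_unequal_variances(1 / 3, 1 / 3, sigma)
        rho1, rho2 = (sigma[1] / sigma[0]) ** 2, (sigma[2] / sigma[0]) ** 2
        head1 = (1 / 3) * sol.design.p[0][1] * sol.design.p[0][0] / (
            sol.design.p[0][1] + rho1 * sol.design.p[0][0])
        tail2 = (1 / 3) * sol.design.p[2][2] * sol.design.p[2][0] / (
            sol.design.p[2][2] + rho2 * sol.design.p[2][0])
        best, arg = np.inf, None
        for p12 in np.arange(0.002, 1, 0.002):
            for p22 in np.arange(0.002, 1 - p12, 0.002):
                p02 = 1 - p12 - p22
                pr1 = head1 + (1 / 3) * p12 * p02 / (p12 + rho1 * p02)
                pr2 = tail2 + (1 / 3) * p22 * p02 / (p22 + rho2 * p02)
                v = max(1 / pr1, 1 / pr2)
                if v < best:
                    best, arg = v, (p02, p12, p22)
        # the surface is very flat: the coarse grid argmin wobbles, so the
        # solver must land near the grid optimum and do at least as well
        assert sol.design.p[1] == pytest.approx(arg, abs=1.5e-2)
        assert sol.objective <= best * (1 + 1e-6)


class TestSumOfVariances:
    def test_symmetric_case_coincides_with_minmax(self):
        sol = optimize_sum_of_variances(1 / 3, 1 / 3)
        assert sol.design.p[1] == pytest.approx(SQRT_K, abs=1e-6)

    def test_control_share_matches_minmax_at_symmetry(self):
        # with r1 = r3 the two criteria share the optimum, control included
        s_sum = optimize_sum_of_variances(0.2, 0.6)
        s_max = optimize_case3_cc(0.2, 0.6)
        assert s_sum.design.p[1][0] >= s_max.design.p[1][0] - 1e-9
        assert s_sum.design.p[1] == pytest.approx(s_max.design.p[1], abs=1e-6)

    def test_arm_shifts_away_from_symmetry(self):
        # relative to minmax, the sum criterion favors the arm whose own
        # periods are smaller: fewer patients on arm 1 when r1 < r3 and
        # vice versa (verified against dense grid searches of both raw
        # objectives)
        s_sum, s_max = optimize_sum_of_variances(0.1, 0.7), optimize_case3_cc(0.1, 0.7)
        assert s_sum.design.p[1][1] < s_max.design.p[1][1]
        assert s_sum.design.p[1][2] > s_max.design.p[1][2]
        s_sum, s_max = optimize_sum_of_variances(0.3, 0.55), optimize_case3_cc(0.3, 0.55)
        assert s_sum.design.p[1][1] > s_max.design.p[1][1]
        assert s_sum.design.p[1][2] < s_max.design.p[1][2]

    def test_first_order_condition_on_the_simplex(self):
        sol = optimize_sum_of_variances(0.2, 0.6)
        r1, r2 = 0.2, 0.6
        r3 = 1 - r1 - r2

        def total(p12, p22):
            p02 = 1 - p12 - p22
            return (1 / (r1 / 4 + r2 * g(p12, p02))
                    + 1 / (r3 / 4 + r2 * g(p22, p02)))

        _, p12, p22 = sol.design.p[1]
        h = 1e-6
        g1 = (total(p12 + h, p22) - total(p12 - h, p22)) / (2 * h)
        g2 = (total(p12, p22 + h) - total(p12, p22 - h)) / (2 * h)
        assert math.hypot(g1, g2) < 1e-5

    def test_objective_is_the_sum(self):
        sol = optimize_sum_of_variances(0.25, 0.5)
        rep = var_stratified_cc(sol.design)
        assert sol.objective == pytest.approx(rep.var_arm1 + rep.var_arm2, rel=1e-12)
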