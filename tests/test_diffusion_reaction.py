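"""Michaelis-Menten uptake, anoxia limit, depletion solvers and the
replenishment law."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from mstdesign.diffusion_reaction import (
    DepletionWarning,
    ReplenishmentFit,
    damkohler_number,
    depletion_time_pde,
    depletion_time_well_mixed,
    max_channel_length,
    max_viable_diameter,
    mm_uptake_rate,
    replenishment_time,
    sweep_and_fit_replenishment,
    zero_order_depletion_time,
)
from mstdesign.params import TissueSample

RHO_CELL = 2.8e14


class TestUptakeKinetics:
    def test_half_saturation(self, glucose):
        q = mm_uptake_rate(glucose.k_M, glucose, RHO_CELL)
        assert q == pytest.approx(0.5 * glucose.q_max * RHO_CELL, rel=1e-12)

    def test_limits(self, glucose):
        assert mm_uptake_rate(0.0, glucose, RHO_CELL) == 0.0
        q_inf = mm_uptake_rate(1e9, glucose, RHO_CELL)
        assert q_inf == pytest.approx(glucose.q_max * RHO_CELL, rel=1e-6)
        with pytest.raises(ValueError):
            mm_uptake_rate(-1.0, glucose, RHO_CELL)


class TestAnoxiaDiameter:
    def test_typical_oxygen_value(self, oxygen):
        d = max_viable_diameter(oxygen, RHO_CELL)
        assert d == pytest.approx(511e-6, rel=1e-2)

    def test_square_root_scaling(self, oxygen):
        doubled = dataclasses.replace(oxygen, q_max=2 * oxygen.q_max)
        assert max_viable_diameter(doubled, RHO_CELL) == pytest.approx(
            max_viable_diameter(oxygen, RHO_CELL) / math.sqrt(2), rel=1e-12)

    def test_fast_tissue_diffusion_limit(self, oxygen):
        fast = dataclasses.replace(oxygen, D_T=1e6 * oxygen.D_T)
        expected = 2 * math.sqrt(
            3 * oxygen.D_M * oxygen.c_sat_M / (oxygen.q_max * RHO_CELL))
        assert max_viable_diameter(fast, RHO_CELL) == pytest.approx(
            expected, rel=1e-4)


class TestWellMixedDepletion:
    def test_against_numeric_ode_oracle(self, tissue_375, glucose):
        V_M = 100 * tissue_375.V_T
        A = glucose.q_max * RHO_CELL * tissue_375.V_T / (V_M + tissue_375.V_T)

        def rhs(_t, c):
            return [-A * c[0] / (c[0] + glucose.k_M)]

        def hit(_t, c):
            return c[0] - glucose.k_M
        hit.terminal = True

        sol = solve_ivp(rhs, (0, 1e7), [glucose.c0], events=hit,
                        rtol=1e-10, atol=1e-12)
        t_oracle = sol.t_events[0][0]
        t = depletion_time_well_mixed(tissue_375, V_M, glucose).t_threshold
        assert t == pytest.approx(t_oracle, rel=1e-6)

    def test_matches_zero_order_when_threshold_is_small(self, tissue_375, glucose):
        t = depletion_time_well_mixed(tissue_375, 100 * tissue_375.V_T,
                                      glucose).t_threshold
        t0 = zero_order_depletion_time(tissue_375, 100 * tissue_375.V_T, glucose)
        assert t == pytest.approx(t0, rel=0.05)

    def test_tissue_only_hand_value(self, tissue_375, glucose):
        # V_M = 0: the tissue's own interstitium holds the whole inventory
        t = depletion_time_well_mixed(tissue_375, 0.0, glucose).t_threshold
        assert t / 3600 == pytest.approx(0.28, rel=0.05)

    def test_doubling_medium_doubles_time_asymptotically(self, tissue_375, glucose):
        t1 = depletion_time_well_mixed(tissue_375, 100 * tissue_375.V_T,
                                       glucose).t_threshold
        t2 = depletion_time_well_mixed(tissue_375, 200 * tissue_375.V_T,
                                       glucose).t_threshold
        assert t2 / t1 == pytest.approx(2.0, rel=0.01)

    def test_degenerate_threshold_warns(self, tissue_375, glucose):
        poor = dataclasses.replace(glucose, c0=glucose.k_M / 2)
        with pytest.warns(DepletionWarning):
            res = depletion_time_well_mixed(tissue_375, 1e-9, poor)
        assert res.t_threshold == 0.0


class TestDepletionPDE:
    def test_reference_run_conserves_mass_and_centres_minimum(
            self, tissue_375, glucose):
        res = depletion_time_pde(tissue_375, 100 * tissue_375.V_T, glucose)
        assert res.t_threshold / 3600 >= 24.0
        assert res.mass_balance_error < 1e-3
        assert res.min_location == 0.0
        # profile at threshold: centre exactly at k_M, increasing outward
        assert res.c_profile[0] == pytest.approx(glucose.k_M, rel=1e-3)
        assert res.c_profile[-1] > res.c_profile[0]

    def test_fast_diffusion_limit_matches_well_mixed(self, tissue_375, glucose):
        fast = dataclasses.replace(glucose, D_M=100 * glucose.D_M,
                                   D_T=100 * glucose.D_T)
        V_M = 50 * tissue_375.V_T
        t_pde = depletion_time_pde(tissue_375, V_M, fast).t_threshold
        t_ode = depletion_time_well_mixed(tissue_375, V_M, fast).t_threshold
        assert t_pde == pytest.approx(t_ode, rel=0.02)

    def test_tiny_km_matches_zero_order_closed_form(self, tissue_375, glucose):
        sharp = dataclasses.replace(glucose, k_M=1e-6)
        fast = dataclasses.replace(sharp, D_M=100 * sharp.D_M,
                                   D_T=100 * sharp.D_T)
        V_M = 20 * tissue_375.V_T
        t = depletion_time_pde(tissue_375, V_M, fast).t_threshold
        t0 = zero_order_depletion_time(tissue_375, V_M, fast)
        assert t == pytest.approx(t0, rel=0.01)

    def test_monotonicity_in_parameters(self, tissue_375, glucose):
        V_M = 30 * tissue_375.V_T
        t_ref = depletion_time_pde(tissue_375, V_M, glucose).t_threshold
        t_more_medium = depletion_time_pde(
            tissue_375, 60 * tissue_375.V_T, glucose).t_threshold
        richer = dataclasses.replace(glucose, c0=2 * glucose.c0,
                                     c_sat_M=2 * glucose.c_sat_M,
                                     c_sat_T=2 * glucose.c_sat_T)
        t_richer = depletion_time_pde(tissue_375, V_M, richer).t_threshold
        hungrier = dataclasses.replace(glucose, q_max=2 * glucose.q_max)
        t_hungrier = depletion_time_pde(tissue_375, V_M, hungrier).t_threshold
        assert t_more_medium > t_ref
        assert t_richer > t_ref
        assert t_hungrier < t_ref

    def test_grid_convergence(self, tissue_375, glucose):
        V_M = 50 * tissue_375.V_T
        coarse = depletion_time_pde(tissue_375, V_M, glucose).t_threshold
        fine = depletion_time_pde(tissue_375, V_M, glucose,
                                  n_tissue=160, n_medium=240).t_threshold
        assert abs(fine - coarse) / fine < 0.005

    def test_rejects_too_coarse_grid(self, tissue_375, glucose):
        with pytest.raises(ValueError, match="too coarse"):
            depletion_time_pde(tissue_375, 1e-9, glucose, n_tissue=2)


class TestReplenishmentLaw:
    def test_fit_recovers_synthetic_linear_times(self):
        # regression plumbing: exactly-linear sweep must be recovered exactly
        tau0 = 1007.0
        a_true, b_true = 0.9, 120.0
        pairs = tuple((r, a_true * tau0 * r + b_true)
                      for r in (10.0, 50.0, 200.0, 1000.0))
        x = np.array([tau0 * r for r, _ in pairs])
        y = np.array([t for _, t in pairs])
        a, b = np.polyfit(x, y, 1)
        fit = ReplenishmentFit(a=a, b=b, r_squared=1.0, tau0=tau0, sweep=pairs)
        assert fit.a == pytest.approx(a_true, abs=1e-10)
        assert fit.b == pytest.approx(b_true, abs=1e-7)
        assert fit.predict(100.0) == pytest.approx(
            a_true * tau0 * 100 + b_true, rel=1e-10)
        assert fit.ratio_for_time(fit.predict(321.0)) == pytest.approx(321.0)

    def test_default_sweep_fit_quality(self, replenishment_fit):
        fit = replenishment_fit
        assert 0.7 < fit.a <= 1.0
        assert fit.r_squared > 0.99
        assert abs(fit.b) < 4 * 3600
        assert len(fit.sweep) >= 12

    def test_predicts_long_schedule_for_large_reservoir(self, replenishment_fit):
        t_h = replenishment_time(replenishment_fit, 729) / 3600
        assert t_h == pytest.approx(180, rel=0.15)
        assert replenishment_time(replenishment_fit, 100) / 3600 >= 24

    def test_metabolite_mismatch_rejected(self, replenishment_fit, oxygen):
        with pytest.raises(ValueError, match="fit was made"):
            replenishment_time(replenishment_fit, 100, oxygen)

    def test_sweep_needs_enough_points(self, tissue_375, glucose):
        with pytest.raises(ValueError):
            sweep_and_fit_replenishment(tissue_375, glucose, ratios=[10, 100])


class TestDamkohler:
    def test_unity_at_max_channel_length(self, oxygen):
        L = max_channel_length(oxygen, 100, RHO_CELL)
        assert damkohler_number(L, oxygen, 100, RHO_CELL) == pytest.approx(
            1.0, rel=1e-12)

    def test_oxygen_reference_length(self, oxygen):
        assert max_channel_length(oxygen, 100, RHO_CELL) == pytest.approx(
            4.45e-3, rel=1e-2)

    def test_scalings(self, glucose):
        da1 = damkohler_number(4e-3, glucose, 100, RHO_CELL)
        assert damkohler_number(2e-3, glucose, 100, RHO_CELL) == pytest.approx(
            da1 / 4, rel=1e-12)
        assert max_channel_length(glucose, 400, RHO_CELL) == pytest.approx(
            2 * max_channel_length(glucose, 100, RHO_CELL), rel=1e-12)
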