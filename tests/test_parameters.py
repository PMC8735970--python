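"""Parameter derivation: diffusion-limited binding, lifetime rates, the
steady-state binding equilibrium, and the expression-rate chain that
reproduces the published parameter tables."""

import math

import numpy as np
import pytest

from selectorswitch.parameters import (
    ObservableSet, ParameterSet, calibrate_protein_rates_to_frap,
    derive_expression_rates, derive_parameter_set, diffusion_limited_rate,
    rate_from_mean_lifetime, solve_binding_equilibrium, round_sig,
    _frap_half_time)
from selectorswitch.deterministic import steady_state_observables
from selectorswitch.presets import OBSERVABLES, STABLE_4B, UNSTABLE_4B


class TestDiffusionLimitedRate:
    @pytest.mark.parametrize("sigma,D,V,expected", [
        (0.01, 1.0, 4.0, 0.0314159),   # measured geometry -> ~0.03 at 1 s.f.
        (0.01, 2.0, 4.0, 0.0628318),
    ])
    def test_closed_form(self, sigma, D, V, expected):
        assert diffusion_limited_rate(sigma, D, V) == pytest.approx(expected,
                                                                    rel=1e-5)

    def test_vanishing_cross_section(self):
        assert diffusion_limited_rate(1e-12, 1.0, 4.0) < 1e-11

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            diffusion_limited_rate(0.0, 1.0, 4.0)


class TestLifetimeRate:
    def test_mean_lifetime_convention(self):
        # 20-min mean lifetime -> 0.00083 at two significant figures
        assert rate_from_mean_lifetime(1200.0) == pytest.approx(1 / 1200)
        assert round_sig(rate_from_mean_lifetime(1200.0), 2) == 0.00083
        assert rate_from_mean_lifetime(3600.0) == pytest.approx(2.78e-4,
                                                                rel=1e-2)

    def test_long_lifetime_limit(self):
        assert rate_from_mean_lifetime(1e15) == pytest.approx(0.0, abs=1e-14)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            rate_from_mean_lifetime(0.0)


def damped_iteration_equilibrium(C_total, fO, bO, bT, NT, tol=1e-12):
    """Independent oracle: damped fixed-point iteration for the free pool."""
    x = C_total
    for _ in range(100000):
        theta_T = fO * x / (fO * x + bT)
        theta_O = fO * x / (fO * x + bO)
        x_new = C_total - NT * theta_T - theta_O
        x = 0.5 * x + 0.5 * max(x_new, 0.0)
        if abs(x_new - x) < tol * max(1.0, x):
            break
    return x


class TestBindingEquilibrium:
    def test_matches_damped_iteration_oracle(self):
        eq = solve_binding_equilibrium(900.0, UNSTABLE_4B, "noncoop")
        x_oracle = damped_iteration_equilibrium(900.0, 0.03, 100, 100, 500)
        assert eq.C_free == pytest.approx(x_oracle, rel=1e-6)
        assert eq.C_free == pytest.approx(803.0, abs=1.0)
        assert eq.theta_O == pytest.approx(0.194, abs=0.002)

    def test_strong_own_promoter_binding(self):
        p = UNSTABLE_4B.replace(bO=0.1)
        eq = solve_binding_equilibrium(900.0, p, "noncoop")
        x_oracle = damped_iteration_equilibrium(900.0, 0.03, 0.1, 100, 500)
        assert eq.C_free == pytest.approx(x_oracle, rel=1e-6)
        assert eq.theta_O == pytest.approx(0.996, abs=0.002)

    def test_no_binding_limit(self):
        p = UNSTABLE_4B.replace(bO=1e12, bT=1e12)
        eq = solve_binding_equilibrium(900.0, p, "noncoop")
        assert eq.C_free == pytest.approx(900.0, rel=1e-6)
        assert eq.theta_O == pytest.approx(0.0, abs=1e-8)

    def test_conservation_residual(self):
        eq = solve_binding_equilibrium(900.0, UNSTABLE_4B, "noncoop")
        assert abs(eq.residual) < 1e-8
        total = eq.C_free + eq.nT_bound_mean + eq.own_bound_mean
        assert total == pytest.approx(900.0, rel=1e-10)

    def test_cooperative_occupancy_stoichiometry(self):
        p = UNSTABLE_4B.replace(b1=1.0, b2=1.0)
        eq = solve_binding_equilibrium(900.0, p, "coop")
        # doubly bound promoter sequesters two molecules
        assert 0 < eq.theta_O < 1
        assert eq.own_bound_mean > eq.theta_O


class TestExpressionRateDerivation:
    """The derivation chain reproduces the printed tables within 2%."""

    def test_unstable_switch_row(self):
        eq = solve_binding_equilibrium(900.0, UNSTABLE_4B, "noncoop")
        fM, bC = derive_expression_rates(OBSERVABLES, eq, fC_given=0.0274)
        assert fM == pytest.approx(0.0302, rel=0.02)
        assert bC == pytest.approx(0.00024, rel=0.02)

    def test_stable_switch_row(self):
        eq = solve_binding_equilibrium(900.0, STABLE_4B, "noncoop")
        fM, bC = derive_expression_rates(OBSERVABLES, eq, fC_given=0.0261)
        assert fM == pytest.approx(0.0059, rel=0.02)
        assert bC == pytest.approx(0.00023, rel=0.02)

    def test_fully_occupied_promoter(self):
        eq = solve_binding_equilibrium(900.0, UNSTABLE_4B, "noncoop")
        eq.theta_O = 1.0
        fM, _ = derive_expression_rates(OBSERVABLES, eq, fC_given=0.0274)
        assert fM == pytest.approx(OBSERVABLES.M_ss / 1200.0)

    def test_round_trip_through_ode(self):
        """Derived rates reproduce the input observables at the ON state."""
        for bO in (100.0, 0.1):
            p = derive_parameter_set(OBSERVABLES, bO=bO, bT=100.0, fC=0.0274)
            M, C_total, _th, _nT = steady_state_observables(p, "noncoop")
            assert M == pytest.approx(OBSERVABLES.M_ss, rel=0.01)
            assert C_total == pytest.approx(OBSERVABLES.C_total, rel=0.01)


class TestFrapCalibration:
    def test_self_consistency_round_trip(self):
        """Calibrated (fC, bC) reproduce the target half-time to <= 1%."""
        target = 83 * 60.0
        fC, bC = calibrate_protein_rates_to_frap(STABLE_4B, target)
        achieved = _frap_half_time(STABLE_4B, ObservableSet(), bC, fC)
        assert achieved == pytest.approx(target, rel=0.01)
        eq = solve_binding_equilibrium(900.0, STABLE_4B, "noncoop")
        assert fC * 7.0 == pytest.approx(bC * eq.C_free, rel=1e-8)

    def test_known_pair_recovered(self):
        """Calibrating to the half-time generated by a known pair returns it."""
        eq = solve_binding_equilibrium(900.0, STABLE_4B, "noncoop")
        bC_true = 3e-4
        fC_true = bC_true * eq.C_free / 7.0
        t_half = _frap_half_time(STABLE_4B, ObservableSet(), bC_true, fC_true)
        fC, bC = calibrate_protein_rates_to_frap(STABLE_4B, t_half)
        assert bC == pytest.approx(bC_true, rel=0.01)
        assert fC == pytest.approx(fC_true, rel=0.01)

    def test_infinite_half_life_limit(self):
        fC, bC = calibrate_protein_rates_to_frap(STABLE_4B, 1e9)
        assert bC < 1e-6

    def test_unattainable_half_life(self):
        with pytest.raises(ValueError):
            calibrate_protein_rates_to_frap(STABLE_4B, 1e-3)


class TestParameterSetValidation:
    def test_rejects_negative_rates(self):
        with pytest.raises(ValueError):
            ParameterSet(fO=-1.0)

    def test_rejects_slow_unbinding_violation(self):
        with pytest.raises(ValueError):
            ParameterSet(bO=1.0, bO_s=2.0)

    def test_missing_rate_named_in_error(self):
        p = ParameterSet()
        with pytest.raises(ValueError, match="b1"):
            p.require("b1")
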