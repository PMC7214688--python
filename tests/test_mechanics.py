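"""Force laws of the MTU elements and the contraction force balance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from myophos import (MTUKinematics, ce_force, contraction_velocity,
                     hill_coefficients, isometric_force_length,
                     passive_equilibrium, pee_force, see_force,
                     serial_damping_coefficient)
from myophos.mechanics import _balance_residual


class TestForceLength:
    def test_maximum_at_optimal_length(self, gas_plus):
        assert isometric_force_length(gas_plus.lCEopt, gas_plus) == 1.0

    def test_one_width_below_optimum_gives_inverse_e(self, gas_plus):
        lce = gas_plus.lCEopt * (1.0 - gas_plus.dW_asc)
        assert isometric_force_length(lce, gas_plus) == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_descending_limb_value(self, gas_plus):
        # 20% beyond optimum on the descending limb; frozen from the
        # closed form exp(-(0.2/0.330)**2.36)
        assert isometric_force_length(0.02376, gas_plus) == pytest.approx(0.735859, abs=1e-5)

    def test_rejects_nonpositive_length(self, gas_plus):
        with pytest.raises(ValueError):
            isometric_force_length(0.0, gas_plus)

    @given(st.floats(0.4, 1.8))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_bounded_and_maximal_only_at_optimum(self, lrel):
        from myophos import get_preset
        p = get_preset("GAS_plus")
        f = isometric_force_length(lrel * p.lCEopt, p)
        assert 0.0 < f <= 1.0
        if abs(lrel - 1.0) > 1e-2:  # away from the underflow region of the bell
            assert f < 1.0


class TestPEE:
    def test_zero_at_slack(self, gas_plus):
        assert pee_force(gas_plus.L_PEE * gas_plus.lCEopt, gas_plus) == 0.0

    def test_normalization_point(self, gas_plus):
        lce = gas_plus.lCEopt * (1.0 + gas_plus.dW_des)
        expected = gas_plus.F_PEE * gas_plus.Fmax  # 17.955 N for GAS+
        assert pee_force(lce, gas_plus) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(17.955, abs=1e-3)

    def test_halfway_power_law(self, gas_plus):
        p = gas_plus
        slack = p.L_PEE * p.lCEopt
        top = p.lCEopt * (1.0 + p.dW_des)
        halfway = 0.5 * (slack + top)
        expected = p.F_PEE * p.Fmax * 0.5**p.nu_PEE
        assert pee_force(halfway, p) == pytest.approx(expected, rel=1e-12)

    def test_nondecreasing(self, gas_plus):
        grid = np.linspace(0.5, 1.6, 200) * gas_plus.lCEopt
        vals = [pee_force(l, gas_plus) for l in grid]
        assert np.all(np.diff(vals) >= 0.0)


class TestSEE:
    def test_slack_and_transition(self, pla_plus):
        p = pla_plus
        assert see_force(p.lSEE0, p) == 0.0
        l_nll = (1.0 + p.dU_SEE_nll) * p.lSEE0
        assert see_force(l_nll, p) == pytest.approx(p.dF_SEE0, rel=1e-12)

    def test_pla_linear_stiffness_matches_table(self, pla_plus):
        p = pla_plus
        k = p.dF_SEE0 / (p.dU_SEE_l * p.lSEE0)
        assert k / 1000.0 == pytest.approx(15.6, rel=0.005)  # kN/m

    def test_c1_continuity_at_toe_linear_transition(self, gas_plus):
        p = gas_plus
        l_nll = (1.0 + p.dU_SEE_nll) * p.lSEE0
        h = 1e-8
        d_left = (see_force(l_nll, p) - see_force(l_nll - h, p)) / h
        d_right = (see_force(l_nll + h, p) - see_force(l_nll, p)) / h
        assert abs(d_right - d_left) / d_right < 1e-6

    def test_nondecreasing(self, gas_plus):
        grid = np.linspace(0.95, 1.15, 300) * gas_plus.lSEE0
        vals = [see_force(l, gas_plus) for l in grid]
        assert np.all(np.diff(vals) >= 0.0)


class TestHillCoefficients:
    def test_full_activity_optimal_length(self, gas_plus):
        arel, brel = hill_coefficients(1.0, 1.0, gas_plus)
        assert (arel, brel) == (gas_plus.Arel0, gas_plus.Brel0)

    def test_zero_activity_scaling(self, gas_plus):
        arel, brel = hill_coefficients(0.0, 0.9, gas_plus)
        assert arel == pytest.approx(gas_plus.Arel0 / 4.0, rel=1e-12)
        assert brel == pytest.approx(3.0 * gas_plus.Brel0 / 7.0, rel=1e-12)

    def test_scaling_can_be_disabled(self, gas_plus):
        arel, brel = hill_coefficients(0.3, 0.5, gas_plus, activity_scaling=False)
        assert (arel, brel) == (gas_plus.Arel0, gas_plus.Brel0)

    def test_max_shortening_velocities_from_fitted_columns(self, gas_minus, pla_plus):
        assert gas_minus.Brel0 / gas_minus.Arel0 == pytest.approx(80.0, rel=0.01)
        assert pla_plus.Brel0 / pla_plus.Arel0 == pytest.approx(27.4, rel=0.01)


class TestCEForce:
    def test_isometric_point(self, gas_plus):
        p = gas_plus
        for a, lce in [(1.0, p.lCEopt), (0.4, 0.9 * p.lCEopt)]:
            expected = a * isometric_force_length(lce, p) * p.Fmax
            assert ce_force(0.0, a, lce, p) == pytest.approx(expected, rel=1e-12)

    def test_eccentric_asymptote(self, gas_plus):
        p = gas_plus
        f = ce_force(1e6, 1.0, p.lCEopt, p)
        assert f == pytest.approx(p.F_e * p.Fmax, rel=1e-3)

    def test_concentric_branch_matches_hyperbola(self, gas_plus):
        p = gas_plus
        a, lce = 1.0, p.lCEopt
        fisom = isometric_force_length(lce, p)
        arel, brel = hill_coefficients(a, 1.0, p)
        vs = np.linspace(-0.9 * brel * p.lCEopt * (a * fisom + arel) / arel, 0.0, 100)
        forces = [ce_force(v, a, lce, p) for v in vs]
        oracle = [p.Fmax * ((a * fisom + arel) / (1.0 - v / (brel * p.lCEopt)) - arel)
                  for v in vs]
        np.testing.assert_allclose(forces, oracle, rtol=1e-12)
        assert np.all(np.diff(forces) > 0.0)  # decreasing with shortening speed

    def test_continuous_and_monotone_through_zero(self, gas_plus):
        p = gas_plus
        vs = np.linspace(-0.02, 0.02, 401)
        forces = [ce_force(v, 0.7, 1.05 * p.lCEopt, p) for v in vs]
        assert np.all(np.diff(forces) > 0.0)
        f_left = ce_force(-1e-12, 0.7, 1.05 * p.lCEopt, p)
        f_right = ce_force(1e-12, 0.7, 1.05 * p.lCEopt, p)
        assert f_left == pytest.approx(f_right, abs=1e-6)

    def test_eccentric_slope_ratio(self, gas_plus):
        p = gas_plus
        a, lce = 0.8, p.lCEopt
        h = 1e-9
        s_con = (ce_force(0.0, a, lce, p) - ce_force(-h, a, lce, p)) / h
        s_ecc = (ce_force(h, a, lce, p) - ce_force(0.0, a, lce, p)) / h
        assert s_ecc / s_con == pytest.approx(p.S_e, rel=1e-4)


class TestSerialDamping:
    def test_force_independent_when_r_is_one(self, gas_plus):
        p = gas_plus.replace(R_SDE=1.0)
        d0 = serial_damping_coefficient(0.0, p)
        d1 = serial_damping_coefficient(100.0, p)
        assert d0 == d1
        expected = p.D_SDE * p.Fmax * p.Arel0 / (p.lCEopt * p.Brel0)
        assert d0 == pytest.approx(expected, rel=1e-12)
        assert d0 == pytest.approx(22.53, abs=0.01)

    def test_zero_at_zero_force_when_r_zero(self, gas_plus):
        assert serial_damping_coefficient(0.0, gas_plus.replace(R_SDE=0.0)) == 0.0


class TestContractionVelocity:
    def test_isometric_steady_state_returns_zero(self, gas_plus):
        p = gas_plus
        a = 0.6
        # find lCE where SEE force balances active + passive force exactly
        def net(lce):
            return (a * p.Fmax * isometric_force_length(lce, p) + pee_force(lce, p)
                    - see_force(0.126 - lce, p))
        lce = brentq(net, 0.01, 0.126 - p.lSEE0, xtol=1e-15)
        v = contraction_velocity(MTUKinematics(0.126, 0.0, lce), a, p)
        assert v == 0.0

    def test_root_satisfies_balance(self, gas_plus):
        p = gas_plus
        v = contraction_velocity(MTUKinematics(0.126, 0.0, 0.9 * p.lCEopt), 0.5, p)
        res = _balance_residual(v, 0.126, 0.0, 0.9 * p.lCEopt, 0.5, p)
        assert abs(res) < 1e-9 * p.Fmax

    def test_agrees_with_bisection_oracle(self, gas_plus):
        p = gas_plus
        v = contraction_velocity(MTUKinematics(0.126, 0.0, 0.9 * p.lCEopt), 0.5, p)
        g = lambda x: _balance_residual(x, 0.126, 0.0, 0.9 * p.lCEopt, 0.5, p)
        lo, hi = (0.0, 1.0) if g(0.0) < 0 else (-1.0, 0.0)
        v_oracle = brentq(g, lo, hi, xtol=1e-13)
        assert abs(v - v_oracle) < 1e-8

    def test_random_states_match_bisection_oracle(self, gas_plus, pla_plus):
        rng = np.random.default_rng(42)
        for p in (gas_plus, pla_plus):
            for _ in range(150):
                lce = p.lCEopt * rng.uniform(0.6, 1.4)
                strain = rng.uniform(0.0, 0.12)
                lmtu = p.lSEE0 * (1.0 + strain) + lce
                vmtu = rng.uniform(-0.05, 0.05)
                a = rng.uniform(0.0, 1.0)
                v = contraction_velocity(MTUKinematics(lmtu, vmtu, lce), a, p)
                g = lambda x: _balance_residual(x, lmtu, vmtu, lce, a, p)
                if g(0.0) == 0.0:
                    assert v == 0.0
                    continue
                # expand the oracle bracket until it straddles the root
                if g(0.0) < 0:
                    hi = 1e-3
                    while g(hi) < 0:
                        hi *= 2.0
                    lo = -1e-12
                else:
                    lo = -1e-3
                    while g(lo) > 0:
                        lo *= 2.0
                    hi = 1e-12
                v_oracle = brentq(g, lo, hi, xtol=1e-13)
                assert abs(v - v_oracle) < 1e-8
                # branch sign consistency
                assert v * g(0.0) <= 0.0


class TestPassiveEquilibrium:
    def test_balance_residual_tiny(self, gas_plus):
        p = gas_plus
        lce = passive_equilibrium(0.126, p.q_min, p)
        res = (p.q_min * p.Fmax * isometric_force_length(lce, p) + pee_force(lce, p)
               - see_force(0.126 - lce, p))
        assert abs(res) < 1e-10 * p.Fmax

    def test_degenerate_short_mtu_returns_see_slack_boundary(self, gas_plus):
        p = gas_plus
        lmtu = p.lSEE0 + 0.5 * p.L_PEE * p.lCEopt  # both elements slack
        assert passive_equilibrium(lmtu, 0.0, p) == pytest.approx(lmtu - p.lSEE0)

    def test_equilibrium_force_monotone_in_mtu_length(self, pla_plus):
        p = pla_plus
        forces = []
        for lmtu in np.linspace(0.110, 0.130, 50):
            lce = passive_equilibrium(lmtu, p.q_min, p)
            forces.append(see_force(lmtu - lce, p))
        assert np.all(np.diff(forces) >= -1e-12)

    def test_pla_longest_length_passive_force_below_ten_percent(self, pla_plus):
        p = pla_plus
        lce = passive_equilibrium(0.124, 0.0, p)
        assert see_force(0.124 - lce, p) < 0.10 * p.Fmax

    def test_rejects_mtu_shorter_than_tendon(self, gas_plus):
        with pytest.raises(ValueError):
            passive_equilibrium(0.05, 0.0, gas_plus)
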