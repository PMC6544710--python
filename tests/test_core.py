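"""Unit tests for the single-block MHH model: rates, steady states, currents."""

import numpy as np
import pytest

import mhhnet as M
from mhhnet.core import RateConvention, gate_rates, mhh_rhs
from mhhnet.reference_states import REFERENCE_EQUILIBRIA

CC = RateConvention.CONTINUATION_CONSISTENT
AP = RateConvention.AS_PRINTED


class TestRateConstants:
    @pytest.mark.parametrize(
        "E, gate, which, expected",
        [
            (-25.0, "m", 1, 0.03),     # exponent exactly zero: beta = 0.015*2
            (-43.0, "h", 0, 0.024),    # exponent exactly zero: alpha = 0.012*2
            (-45.0, "n", 0, 0.072),    # removable 0/0 limit: 0.006*12
        ],
    )
    def test_exact_values(self, E, gate, which, expected):
        assert M.rate_constants(E, gate, CC)[which] == pytest.approx(expected, rel=1e-12)

    def test_alpha_n_limit_continuous(self):
        """The series patch at the singularity joins the formula smoothly."""
        near = M.rate_constants(-45.0 + 5e-7, "n", CC)[0]
        off = M.rate_constants(-45.0 + 1e-5, "n", CC)[0]
        assert near == pytest.approx(0.072, abs=1e-6)
        assert off == pytest.approx(near, rel=1e-5)

    def test_sign_conventions_differ_only_in_alpha_n(self):
        E = np.linspace(-80.0, 20.0, 41)
        a_cc, b_cc = gate_rates(E, CC)
        a_ap, b_ap = gate_rates(E, AP)
        np.testing.assert_array_equal(b_cc, b_ap)
        np.testing.assert_array_equal(a_cc[:, [0, 1, 3, 4]], a_ap[:, [0, 1, 3, 4]])
        # literal form goes negative above the singularity; default stays positive
        assert np.all(a_cc[:, 2] > 0)
        assert np.any(a_ap[:, 2] < 0)

    def test_unknown_gate_error_names_valid_gates(self):
        with pytest.raises(ValueError, match="m, h, n, mS, hS"):
            M.rate_constants(-50.0, "x")

    def test_nonfinite_E_rejected(self):
        with pytest.raises(ValueError):
            M.rate_constants(np.nan, "m")


class TestSteadyStateGates:
    @pytest.mark.parametrize(
        "E, index, expected",
        [
            (-16.826666, 0, 0.993461),  # m at the first Hopf equilibrium
            (-28.153602, 2, 0.643778),  # n at the limit-point equilibrium
        ],
    )
    def test_reference_equilibrium_values(self, E, index, expected):
        g = M.steady_state_gates(E, CC)
        assert g[index] == pytest.approx(expected, abs=5e-7)

    def test_h_infinity_differs_from_reference_print(self):
        """Documented inconsistency: the local inactivation kinetics give
        h_inf ~ 0.0104 at the first Hopf E, not the reference 0.009702."""
        g = M.steady_state_gates(-16.826666, AP)
        assert g[1] == pytest.approx(0.01038, abs=2e-5)
        assert abs(g[1] - 0.009702) / 0.009702 > 5e-2

    def test_all_components_in_open_interval(self):
        rng = np.random.default_rng(7)
        for E in rng.uniform(-100.0, 60.0, 200):
            g = M.steady_state_gates(E, CC)
            assert np.all(g > 0.0) and np.all(g < 1.0)

    def test_fixed_point_of_gate_odes_at_clamped_E(self):
        """alpha(1-g) - beta g vanishes at g = alpha/(alpha+beta)."""
        rng = np.random.default_rng(11)
        E = rng.uniform(-100.0, 60.0, 1000)
        a, b = gate_rates(E, CC)
        g = M.steady_state_gates(E, CC)
        np.testing.assert_allclose(a * (1 - g) - b * g, 0.0, atol=1e-12)


class TestMembraneRHS:
    def test_gate_derivatives_vanish_at_steady_state(self, tg_params):
        for E in (-70.0, -45.0, -16.826666, 0.0):
            st = M.MHHState.at_steady_state(E, CC)
            d = M.membrane_rhs(st, 0.0, tg_params, CC)
            np.testing.assert_allclose(d[1:], 0.0, atol=1e-12)

    def test_reference_hopf_state_nearly_stationary(self, tg_params):
        """dE/dt ~ 0 at the printed first-Hopf state with its printed current
        (within the 6-decimal rounding of the state)."""
        st = np.array(REFERENCE_EQUILIBRIA[0].state)
        d = M.membrane_rhs(st, 37.416140, tg_params, CC)
        assert abs(d[0]) < 1e-2  # mV/ms

    def test_derivative_matches_integrated_flow(self, tg_params):
        """Forward-difference of the integrated flow at t=0 equals the RHS."""
        from scipy.integrate import solve_ivp

        rng = np.random.default_rng(3)
        y0 = np.concatenate([[-52.0], rng.uniform(0.1, 0.9, 5)])
        I = 12.0
        f0 = M.membrane_rhs(y0, I, tg_params, CC)
        h = 1e-4
        sol = solve_ivp(
            lambda t, y: mhh_rhs(y, I, tg_params, CC), (0, h), y0,
            rtol=1e-12, atol=1e-12,
        )
        fd = (sol.y[:, -1] - y0) / h
        np.testing.assert_allclose(fd, f0, rtol=1e-3, atol=1e-8)

    def test_nonfinite_state_rejected(self, tg_params):
        with pytest.raises(ValueError):
            M.membrane_rhs(np.array([np.inf, 0.5, 0.5, 0.5, 0.5, 0.5]), 0.0, tg_params)


class TestCurrentBalance:
    def test_vanishes_when_all_reversal_potentials_equal_E(self):
        p = M.BlockParams(ENa=-20.0, EK=-20.0, EL=-20.0)
        st = np.array([-20.0, 0.5, 0.5, 0.5, 0.5, 0.5])
        assert M.ionic_current_balance(st, p) == 0.0

    def test_units_pA_equals_nS_times_mV(self, tg_params):
        """Doubling every conductance doubles the balance current."""
        st = np.array([-30.0, 0.9, 0.1, 0.6, 0.4, 0.3])
        doubled = M.BlockParams(gNaf=50.0, gK=40.0, gL=10.0, gNaS=200.0)
        assert M.ionic_current_balance(st, doubled) == pytest.approx(
            2.0 * M.ionic_current_balance(st, tg_params), rel=1e-14
        )

    def test_solve_conductance_round_trip_exact(self, tg_params):
        st = np.array(REFERENCE_EQUILIBRIA[4].state)
        g = M.solve_conductance_from_balance(st, 30.0, tg_params, "NaS")
        assert M.ionic_current_balance(st, tg_params.with_(gNaS=g)) == 30.0

    def test_zero_driving_force_rejected(self, tg_params):
        st = np.array([60.0, 0.5, 0.5, 0.5, 0.5, 0.5])  # E = ENa
        with pytest.raises(ZeroDivisionError):
            M.solve_conductance_from_balance(st, 10.0, tg_params, "NaS")

    def test_unknown_channel_rejected(self, tg_params):
        with pytest.raises(ValueError, match="Naf, K, L, NaS"):
            M.solve_conductance_from_balance(np.zeros(6), 0.0, tg_params, "Ca")


class TestReferenceStateAlgebra:
    """Regression-documenting audit of the six reference equilibria."""

    def test_m_n_mS_match_steady_state_formulas(self):
        for ref in REFERENCE_EQUILIBRIA:
            g = M.steady_state_gates(ref.state[0], CC)
            for idx, printed in ((0, ref.state[1]), (2, ref.state[3]), (3, ref.state[4])):
                assert abs(g[idx] - printed) / printed < 1e-4, ref.label

    def test_h_hS_documented_mismatch(self):
        """The reference h/hS columns are NOT reproduced by the local
        inactivation kinetics; the mismatch itself is the invariant."""
        for ref in REFERENCE_EQUILIBRIA:
            g = M.steady_state_gates(ref.state[0], CC)
            assert abs(g[4] - ref.state[5]) / ref.state[5] > 1e-2, ref.label

    def test_current_balance_recovers_bifurcation_parameters(self, tg_params):
        for ref in REFERENCE_EQUILIBRIA:
            st = np.array(ref.state)
            if ref.branch == "I0":
                val = M.ionic_current_balance(st, tg_params)
            else:
                val = M.solve_conductance_from_balance(st, 30.0, tg_params, "NaS")
            assert abs(val - ref.param_value) / abs(ref.param_value) < 1e-3, ref.label


class TestCapacitance:
    def test_permittivity_ratio_matches_reference_print(self):
        spec = M.CapacitanceSpec()
        cm = M.capacitance_from_permittivity(spec, "S1")
        assert cm == pytest.approx(5.0 * 4.07e7 / 2.01e7, rel=1e-14)
        assert cm == pytest.approx(10.1245, rel=2e-5)

    def test_reference_block_identity_and_linearity(self):
        spec = M.CapacitanceSpec(epsR_by_block={"A": 3.0, "B": 6.0}, Cm_ref=2.0, ref_block="A")
        assert M.capacitance_from_permittivity(spec, "A") == 2.0
        assert M.capacitance_from_permittivity(spec, "B") == 4.0

    def test_unknown_block_rejected(self):
        with pytest.raises(KeyError):
            M.capacitance_from_permittivity(M.CapacitanceSpec(), "cerebellum")


class TestRatePositivity:
    def test_rates_positive_and_gates_bounded_over_voltage_range(self):
        """Under the default convention every rate is positive and every
        steady-state gate lies strictly inside (0, 1) across the
        physiological voltage range (property-based)."""
        from hypothesis import given, settings, strategies as st

        @settings(derandomize=True, max_examples=200, deadline=None)
        @given(st.floats(min_value=-120.0, max_value=60.0,
                         allow_nan=False, allow_infinity=False))
        def check(E):
            a, b = gate_rates(E, CC)
            assert np.all(a > 0) and np.all(b > 0)
            g = M.steady_state_gates(E, CC)
            assert np.all(g > 0) and np.all(g < 1)

        check()


class TestGateBoundedness:
    def test_random_trajectories_keep_gates_in_unit_interval(self, tg_params):
        """100 random initial states and inputs, integrated jointly as
        independent blocks: gates stay in [0, 1] under the default rates."""
        from scipy.integrate import solve_ivp

        rng = np.random.default_rng(42)
        n = 100
        y0 = np.empty((n, 6))
        y0[:, 0] = rng.uniform(-90.0, 30.0, n)
        y0[:, 1:] = rng.uniform(0.0, 1.0, (n, 5))
        I = rng.uniform(-100.0, 100.0, n)
        sol = solve_ivp(
            lambda t, y: mhh_rhs(y.reshape(n, 6), I, tg_params, CC).ravel(),
            (0.0, 50.0), y0.ravel(), rtol=1e-8, atol=1e-10,
        )
        assert sol.success
        gates = sol.y.reshape(n, 6, -1)[:, 1:, :]
        assert gates.min() >= -1e-9
        assert gates.max() <= 1.0 + 1e-9
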