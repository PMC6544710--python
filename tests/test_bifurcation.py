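"""Tests for equilibrium solving, continuation, bifurcation detection and
normal-form coefficients, against analytic and simulation oracles."""

import numpy as np
import pytest
from scipy.optimize import brentq

import mhhnet as M
from mhhnet.bifurcation import (
    continue_branch,
    detect_bifurcations,
    first_lyapunov_coefficient,
    fold_coefficient,
    hopf_curve_two_param,
    jacobian,
    mhh_system,
    orbit_diagram,
    solve_equilibrium,
)
from mhhnet.core import RateConvention, gate_rates, mhh_rhs, steady_state_gates
from mhhnet.fixtures import circle_hopf_locus, normal_form_fold, normal_form_hopf

CC = RateConvention.CONTINUATION_CONSISTENT


class TestSolveEquilibrium:
    def test_residual_postcondition(self, tg_params):
        for I0 in (-100.0, 0.0, 30.0, 60.0):
            eq = solve_equilibrium(tg_params, I0, guess=-50.0)
            assert eq.residual <= 1e-10

    def test_reduced_problem_against_bisection_oracle(self):
        """With only K and leak currents the equilibrium solves
        gK n_inf(E)^4 (E - EK) + gL (E - EL) = I0; cross-check by brentq."""
        p = M.BlockParams(gNaf=0.0, gNaS=0.0)
        I0 = 12.0

        def scalar(E):
            n = steady_state_gates(E, CC)[2]
            return p.gK * n**4 * (E - p.EK) + p.gL * (E - p.EL) - I0

        oracle = brentq(scalar, -80.0, 20.0, xtol=1e-13)
        eq = solve_equilibrium(p, I0, guess=-60.0)
        assert eq.state[0] == pytest.approx(oracle, abs=1e-9)

    def test_equilibrium_independent_of_capacitance(self, tg_params):
        a = solve_equilibrium(tg_params, 25.0, guess=-50.0)
        b = solve_equilibrium(tg_params.with_(Cm=10.1245), 25.0, guess=-50.0)
        np.testing.assert_allclose(a.state, b.state, atol=1e-12)

    def test_stability_label_matches_spectrum(self, oscillating_params):
        eq = solve_equilibrium(oscillating_params, -38.0, guess=-43.0)
        assert eq.stability == "unstable"
        assert np.max(np.real(eq.eigenvalues)) > 0


class TestJacobian:
    def test_matches_central_finite_differences(self, tg_params):
        rng = np.random.default_rng(17)
        for _ in range(100):
            y = np.concatenate([[rng.uniform(-80, 20)], rng.uniform(0.05, 0.95, 5)])
            J = jacobian(y, tg_params, 0.0, CC)
            Jfd = np.empty((6, 6))
            for i in range(6):
                h = 1e-6 * max(1.0, abs(y[i]))
                yp, ym = y.copy(), y.copy()
                yp[i] += h
                ym[i] -= h
                Jfd[:, i] = (
                    mhh_rhs(yp, 0.0, tg_params, CC) - mhh_rhs(ym, 0.0, tg_params, CC)
                ) / (2 * h)
            np.testing.assert_allclose(J, Jfd, rtol=1e-6, atol=1e-8)

    def test_gate_diagonal_is_minus_alpha_plus_beta(self, tg_params):
        y = np.array([-40.0, 0.5, 0.5, 0.5, 0.5, 0.5])
        J = jacobian(y, tg_params, 0.0, CC)
        a, b = gate_rates(-40.0, CC)
        for i in range(5):
            assert J[i + 1, i + 1] == -(a[i] + b[i])

    def test_capacitance_scales_only_the_E_row(self, tg_params):
        y = np.array([-40.0, 0.7, 0.2, 0.6, 0.4, 0.3])
        J1 = jacobian(y, tg_params, 0.0, CC)
        J2 = jacobian(y, tg_params.with_(Cm=15.0), 0.0, CC)
        np.testing.assert_allclose(J2[0], J1[0] * (5.0 / 15.0), rtol=1e-14)
        np.testing.assert_array_equal(J2[1:], J1[1:])


class TestContinuation:
    def test_stable_linear_system_has_no_bifurcations(self):
        A = np.diag([-1.0, -2.0])

        def f(x, mu):
            return A @ x + np.array([mu, 0.5 * mu])

        br = continue_branch(f, np.zeros(2), -1.0, (-1.0, 1.0), ds=0.2)
        assert detect_bifurcations(br) == []
        assert all(pt.stability == "stable" for pt in br.points)

    def test_fold_recovers_both_sheets_and_limit_point(self):
        f = normal_form_fold()
        br = continue_branch(f, np.array([1.0]), 1.0, (-1.0, 1.0), ds=0.1, direction=-1)
        bps = detect_bifurcations(br)
        assert len(bps) == 1
        assert bps[0].kind == "LimitPoint"
        assert bps[0].param == pytest.approx(0.0, abs=1e-6)
        assert bps[0].coefficient != 0.0
        # both solution sheets x = +-sqrt(mu) traversed
        assert br.states.min() < -0.5 and br.states.max() >= 1.0
        sheet = br.states[:, 0]
        mu = br.params
        np.testing.assert_allclose(sheet**2, np.abs(mu), atol=1e-8)

    @pytest.mark.parametrize("c, sign", [(-1.0, -1), (1.0, +1)])
    def test_hopf_normal_form_detection_and_criticality(self, c, sign):
        f = normal_form_hopf(omega=2.0, c=c)
        br = continue_branch(f, np.zeros(2), -0.5, (-0.5, 0.5), ds=0.1)
        bps = detect_bifurcations(br)
        assert len(bps) == 1
        assert bps[0].kind == "Hopf"
        assert bps[0].param == pytest.approx(0.0, abs=1e-6)
        assert np.sign(bps[0].coefficient) == sign
        assert bps[0].omega == pytest.approx(2.0, rel=1e-8)

    def test_first_lyapunov_coefficient_scales_linearly(self):
        """For dz/dt = (mu+i w)z + c z|z|^2 the computed L1 is linear in c."""
        vals = {}
        for c in (-2.0, -1.0, 1.0, 2.0):
            f = normal_form_hopf(omega=1.5, c=c)
            L1, omega, degen = first_lyapunov_coefficient(
                lambda y: f(y, 0.0), np.zeros(2)
            )
            assert not degen
            vals[c] = L1
        base = vals[1.0]
        for c, L1 in vals.items():
            assert L1 == pytest.approx(c * base, rel=1e-6)

    def test_fold_coefficient_normal_form(self):
        f = normal_form_fold()
        a = fold_coefficient(lambda y: f(y, 0.0), np.zeros(1))
        assert a == pytest.approx(-1.0, rel=1e-5)

    def test_mhh_branch_detects_hopf_pair_in_oscillatory_regime(self, oscillating_params):
        """At gNaS = 280 nS the I0 branch carries two genuine Hopf points
        bounding the oscillation window, subcritical below, supercritical
        above (regression values from this model)."""
        eq = solve_equilibrium(oscillating_params, 0.0, guess=-38.0)
        f, jac, jac_p = mhh_system(oscillating_params, free="I0")
        br = continue_branch(
            f, eq.state, 0.0, (-80.0, 20.0), jac=jac, jac_p=jac_p, ds=1.0,
            direction=-1, max_steps=400,
        )
        hopfs = [b for b in detect_bifurcations(br) if b.kind == "Hopf"]
        assert len(hopfs) == 2
        lo, hi = sorted(hopfs, key=lambda b: b.param)
        assert -57.0 < lo.param < -54.0 and lo.coefficient > 0
        assert -24.5 < hi.param < -22.0 and hi.coefficient < 0
        for b in hopfs:
            # the pair at the critical frequency sits on the imaginary axis
            crit = min(
                (e for e in b.eigenvalues if np.imag(e) > 0),
                key=lambda e: abs(np.imag(e) - b.omega),
            )
            assert abs(np.real(crit)) < 1e-6


class TestHopfCurve:
    def test_recovers_circular_locus(self):
        f = circle_hopf_locus()
        curve = hopf_curve_two_param(f, np.zeros(2), 1.0, 0.0, ds=0.1, max_steps=200)
        r = np.hypot(curve["p1"], curve["p2"])
        assert curve["closed"]
        assert np.max(np.abs(r - 1.0)) < 1e-3

    def test_curve_points_satisfy_equilibrium_residual(self, oscillating_params):
        base = M.BlockParams()

        def f2(x, I0, g):
            return mhh_rhs(np.asarray(x), I0, base.with_(gNaS=float(g)))

        def jx(x, I0, g):
            return jacobian(x, base.with_(gNaS=float(g)), I0)

        eq = solve_equilibrium(oscillating_params, -35.0, guess=-43.0)
        curve = hopf_curve_two_param(
            f2, eq.state, -35.0, 280.0, ds=2.0, max_steps=40, jac_x=jx,
            p2_range=(200.0, 400.0),
        )
        assert len(curve["p1"]) > 10
        for x, p1, p2 in zip(curve["states"], curve["p1"], curve["p2"]):
            resid = np.max(np.abs(f2(x, p1, p2)))
            assert resid < 1e-7


class TestOrbitDiagram:
    def test_fixed_point_regime_matches_equilibrium(self, tg_params):
        od = orbit_diagram(tg_params, "I0", [20.0], t_end=600.0, dt=0.2)
        assert od.classification == ["fixed_point"]
        eq = solve_equilibrium(tg_params, 20.0, guess=-45.0)
        # no extrema survive; the trajectory tail sits on the equilibrium
        assert len(od.extrema[0]) == 0 or np.allclose(od.extrema[0], eq.state[0], atol=0.5)

    def test_periodic_regime_two_extrema_clusters(self, oscillating_params):
        od = orbit_diagram(
            oscillating_params, "I0", [-35.0], t_end=4000.0, dt=0.5,
            transient_frac=0.6,
        )
        assert od.classification[0] in ("periodic", "bursting")
        ext = od.extrema[0]
        assert ext.max() - ext.min() > 10.0  # large relaxation cycle

    def test_unknown_parameter_rejected(self, tg_params):
        with pytest.raises(ValueError):
            orbit_diagram(tg_params, "gK", [1.0])
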