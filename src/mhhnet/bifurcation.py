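"""Equilibrium continuation and bifurcation analysis.

Provides, for the single MHH block (and for arbitrary user ODE systems):

* Newton equilibrium solving with an analytic Jacobian,
* pseudo-arclength predictor-corrector continuation of equilibrium
  branches in one parameter, traversing folds,
* detection and bisection refinement of Hopf and limit (fold) points from
  eigenvalue test functions, with neutral-saddle disambiguation,
* normal-form coefficients: the first Lyapunov coefficient L1 at Hopf
  points (projection method, directional finite differences up to third
  order) and the quadratic coefficient a at folds,
* two-parameter continuation of the Hopf condition (fully extended
  system: equilibrium + critical eigenpair),
* brute-force orbit diagrams (post-transient extrema of a simulated
  trajectory versus a swept parameter).

Test-function conventions: the fold function is det(J) = prod(lambda_i);
the Hopf function is the bialternate-style product prod_{i<j}
(lambda_i + lambda_j), which vanishes both at genuine Hopf points (complex
pair on the axis) and at neutral saddles (two real eigenvalues summing to
zero) — the refined root is classified by whether the critical pair is
complex.

Equilibrium states and fold locations are invariant to the capacitance Cm
(Cm only rescales dE/dt); Hopf locations are not, so the Cm used is
recorded in every Branch's metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from .core import (
    BlockParams,
    MHHState,
    RateConvention,
    gate_rates,
    gate_rates_dE,
    ionic_current_balance,
    membrane_rhs,
    mhh_rhs,
    steady_state_gates,
)
from .network import NetworkConfig, Stimulus, simulate, trim_transient

__all__ = [
    "EquilibriumPoint",
    "BifPoint",
    "Branch",
    "OrbitDiagram",
    "solve_equilibrium",
    "jacobian",
    "continue_branch",
    "detect_bifurcations",
    "first_lyapunov_coefficient",
    "fold_coefficient",
    "hopf_curve_two_param",
    "orbit_diagram",
    "mhh_system",
]

_EIG_BAND = 1e-8  # marginality band for stability labels


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class EquilibriumPoint:
    """One converged equilibrium: state, parameter, spectrum, stability."""

    state: np.ndarray
    param: float
    eigenvalues: np.ndarray
    residual: float
    stability: str  # stable | unstable | marginal

    @staticmethod
    def classify(eigenvalues: np.ndarray) -> str:
        mx = float(np.max(np.real(eigenvalues)))
        if mx < -_EIG_BAND:
            return "stable"
        if mx > _EIG_BAND:
            return "unstable"
        return "marginal"


@dataclass
class BifPoint:
    """A detected bifurcation point on a branch.

    kind is 'Hopf', 'LimitPoint' or 'NeutralSaddle'.  For Hopf points
    ``coefficient`` is the first Lyapunov coefficient L1 (negative =
    supercritical, stable emerging cycle) and ``omega`` the critical
    frequency; for limit points ``coefficient`` is the quadratic normal-form
    coefficient a.  ``degenerate`` flags |L1| below tolerance (possible
    Bautin point).
    """

    kind: str
    param: float
    state: np.ndarray
    eigenvalues: np.ndarray
    coefficient: float | None = None
    omega: float | None = None
    degenerate: bool = False


@dataclass
class Branch:
    """An ordered equilibrium branch plus detected bifurcations and metadata."""

    points: list
    bif_points: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def params(self) -> np.ndarray:
        return np.array([p.param for p in self.points])

    @property
    def states(self) -> np.ndarray:
        return np.array([p.state for p in self.points])

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class OrbitDiagram:
    """Post-transient extrema of an observed variable versus a parameter.

    ``extrema[i]`` collects the local maxima and minima values at
    ``param_values[i]``; ``classification[i]`` is 'fixed_point', 'periodic'
    or 'bursting' (multi-extremum); failed simulations are marked 'missing'.
    """

    param_name: str
    param_values: np.ndarray
    extrema: list
    classification: list
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# MHH single-block system
# ---------------------------------------------------------------------------

def jacobian(state, params: BlockParams, I0: float = 0.0, convention=None) -> np.ndarray:
    """Analytic 6x6 Jacobian of the single-block MHH right-hand side.

    Gate-row structure: d(dg/dt)/dg = -(alpha+beta) exactly;
    d(dg/dt)/dE = alpha'(E)(1-g) - beta'(E) g with rate derivatives from a
    complex step (exact to machine precision).  The applied current I0 does
    not enter the Jacobian; Cm rescales only the E row.
    """
    y = state.as_array() if isinstance(state, MHHState) else np.asarray(state, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("state must be finite")
    E, m, h, n, mS, hS = y
    p = params
    J = np.zeros((6, 6))
    J[0, 0] = -(p.gNaf * m**3 * h + p.gK * n**4 + p.gL + p.gNaS * mS**3 * hS) / p.Cm
    J[0, 1] = -3.0 * p.gNaf * m**2 * h * (E - p.ENa) / p.Cm
    J[0, 2] = -p.gNaf * m**3 * (E - p.ENa) / p.Cm
    J[0, 3] = -4.0 * p.gK * n**3 * (E - p.EK) / p.Cm
    J[0, 4] = -3.0 * p.gNaS * mS**2 * hS * (E - p.ENa) / p.Cm
    J[0, 5] = -p.gNaS * mS**3 * (E - p.ENa) / p.Cm
    a, b = gate_rates(E, convention)
    da, db = gate_rates_dE(E, convention)
    gates = y[1:]
    for i in range(5):
        J[i + 1, 0] = da[i] * (1.0 - gates[i]) - db[i] * gates[i]
        J[i + 1, i + 1] = -(a[i] + b[i])
    return J


def mhh_system(
    params: BlockParams,
    free: str = "I0",
    I0: float = 0.0,
    convention=None,
):
    """(f, jac, jac_p) closures for one MHH block with a free parameter.

    ``free`` is 'I0' (applied current, pA) or 'gNaS' (slow-sodium
    conductance, nS); the other is held at its value in ``params`` / ``I0``.
    The closures accept complex states (needed for normal-form finite
    differences).
    """
    if free == "I0":

        def f(x, p):
            return mhh_rhs(np.asarray(x), p, params, convention)

        def jac(x, p):
            return jacobian(x, params, p, convention)

        def jac_p(x, p):
            v = np.zeros(6)
            v[0] = 1.0 / params.Cm
            return v

    elif free == "gNaS":

        def f(x, p):
            return mhh_rhs(np.asarray(x), I0, params.with_(gNaS=float(np.real(p))), convention)

        def jac(x, p):
            return jacobian(x, params.with_(gNaS=float(np.real(p))), I0, convention)

        def jac_p(x, p):
            x = np.asarray(x)
            E, mS, hS = x[0], x[4], x[5]
            v = np.zeros(6)
            v[0] = -(mS**3) * hS * (E - params.ENa) / params.Cm
            return v

    else:
        raise ValueError("free parameter must be 'I0' or 'gNaS'")
    return f, jac, jac_p


def _balance_at_E(E: float, params: BlockParams, convention=None) -> float:
    """Applied current balancing the membrane equation with gates at steady state."""
    g = steady_state_gates(E, convention)
    y = np.concatenate([[E], np.asarray(g)])
    return float(ionic_current_balance(y, params))


def solve_equilibrium(
    params: BlockParams,
    I0: float,
    guess: float | MHHState | np.ndarray = -60.0,
    convention=None,
    tol: float = 1e-12,
    max_iter: int = 100,
) -> EquilibriumPoint:
    """Equilibrium of one block at applied current I0 (pA).

    The 6-D problem reduces to a scalar one: gates are eliminated via their
    steady states, leaving the current balance in E alone.  A damped Newton
    iteration from the guess (an E value, or a state whose E is used) is
    tried first, falling back to bracketed bisection on an expanding
    interval.  The returned point's full right-hand-side residual is at
    most ``tol`` scaled by Cm (1e-10 by default margin); eigenvalues of the
    analytic Jacobian and a stability label are attached.
    """
    if isinstance(guess, MHHState):
        E = guess.E
    elif np.ndim(guess) > 0:
        E = float(np.asarray(guess)[0])
    else:
        E = float(guess)

    def g(Ev):
        return _balance_at_E(Ev, params, convention) - I0

    converged = False
    for _ in range(max_iter):
        r = g(E)
        if abs(r) < tol:
            converged = True
            break
        dE = 1e-6 * max(1.0, abs(E))
        dr = (g(E + dE) - g(E - dE)) / (2.0 * dE)
        if dr == 0.0 or not np.isfinite(dr):
            break
        step = -r / dr
        step = np.clip(step, -25.0, 25.0)  # damp wild Newton steps
        E = E + step
        if not np.isfinite(E):
            break
    if not converged:
        # expanding bracket search around the guess
        E0 = float(guess.E if isinstance(guess, MHHState) else np.atleast_1d(guess)[0])
        root = None
        for half_width in (5.0, 20.0, 60.0, 150.0):
            lo, hi = E0 - half_width, E0 + half_width
            grid = np.linspace(lo, hi, 121)
            vals = np.array([g(v) for v in grid])
            sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
            if len(sign_change):
                # the bracket nearest the guess
                k = sign_change[np.argmin(np.abs(grid[sign_change] - E0))]
                root = brentq(g, grid[k], grid[k + 1], xtol=1e-14, rtol=8.9e-16)
                break
        if root is None:
            raise RuntimeError(
                f"equilibrium solve failed to converge (last iterate E = {E:.6g} mV)"
            )
        E = float(root)

    state = MHHState.at_steady_state(E, convention).as_array()
    resid = float(np.max(np.abs(membrane_rhs(state, I0, params, convention))))
    eigs = np.linalg.eigvals(jacobian(state, params, I0, convention))
    return EquilibriumPoint(
        state=state,
        param=float(I0),
        eigenvalues=eigs,
        residual=resid,
        stability=EquilibriumPoint.classify(eigs),
    )


# ---------------------------------------------------------------------------
# generic pseudo-arclength continuation
# ---------------------------------------------------------------------------

def _fd_jac(f, x, p, eps=1e-7):
    x = np.asarray(x, dtype=float)
    f0 = np.asarray(f(x, p), dtype=float)
    J = np.empty((len(f0), len(x)))
    for i in range(len(x)):
        step = eps * max(1.0, abs(x[i]))
        xp = x.copy()
        xp[i] += step
        xm = x.copy()
        xm[i] -= step
        J[:, i] = (np.asarray(f(xp, p)) - np.asarray(f(xm, p))) / (2.0 * step)
    return J


def _fd_jac_p(f, x, p, eps=1e-7):
    step = eps * max(1.0, abs(p))
    return (np.asarray(f(x, p + step)) - np.asarray(f(x, p - step))) / (2.0 * step)


def _newton_fixed_p(f, jac, x0, p, tol=1e-12, max_iter=50):
    x = np.asarray(x0, dtype=float).copy()
    for _ in range(max_iter):
        r = np.asarray(f(x, p), dtype=float)
        if np.max(np.abs(r)) < tol:
            return x
        x = x - np.linalg.solve(jac(x, p), r)
    r = np.asarray(f(x, p), dtype=float)
    if np.max(np.abs(r)) < tol * 100:
        return x
    raise RuntimeError("Newton failed to converge at fixed parameter")


def _corrector(f, jac, jac_p, z_pred, tangent, tol=1e-10, max_iter=12):
    """Newton on [f(x,p); tangent . (z - z_pred)] = 0; z = (x, p)."""
    z = z_pred.copy()
    n = len(z) - 1
    for _ in range(max_iter):
        r = np.asarray(f(z[:n], z[n]), dtype=float)
        extra = tangent @ (z - z_pred)
        if np.max(np.abs(r)) < tol and abs(extra) < tol:
            return z
        A = np.empty((n + 1, n + 1))
        A[:n, :n] = jac(z[:n], z[n])
        A[:n, n] = jac_p(z[:n], z[n])
        A[n, :] = tangent
        z = z - np.linalg.solve(A, np.append(r, extra))
    raise RuntimeError("corrector failed")


def _tangent(jac, jac_p, z, prev):
    """Unit tangent of the branch at z, oriented along prev."""
    n = len(z) - 1
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = jac(z[:n], z[n])
    A[:n, n] = jac_p(z[:n], z[n])
    A[n, :] = prev
    rhs = np.zeros(n + 1)
    rhs[n] = 1.0
    t = np.linalg.solve(A, rhs)
    t /= np.linalg.norm(t)
    if t @ prev < 0:
        t = -t
    return t


def continue_branch(
    f: Callable,
    x0,
    p0: float,
    p_range: tuple,
    *,
    jac: Callable | None = None,
    jac_p: Callable | None = None,
    ds: float = 0.5,
    ds_max: float = 5.0,
    ds_min: float = 1e-8,
    max_steps: int = 2000,
    direction: int = +1,
    newton_tol: float = 1e-10,
    meta: dict | None = None,
) -> Branch:
    """Pseudo-arclength continuation of f(x, p) = 0 across ``p_range``.

    Starts from a converged equilibrium at (x0, p0) (re-converged first if
    needed), traverses folds, and records eigenvalues of the state Jacobian
    at every point.  ``direction`` picks the initial sense of the parameter.
    On corrector failure the step is halved down to ``ds_min``; if the floor
    is reached the partial branch is returned with ``meta['status'] =
    'incomplete'``.
    """
    jac = jac or (lambda x, p: _fd_jac(f, x, p))
    jac_p = jac_p or (lambda x, p: _fd_jac_p(f, x, p))
    x0 = _newton_fixed_p(f, jac, np.asarray(x0, dtype=float), p0, tol=newton_tol)
    n = len(x0)
    lo, hi = min(p_range), max(p_range)
    if not (lo <= p0 <= hi):
        raise ValueError("starting parameter must lie inside p_range")

    def make_point(z):
        eigs = np.linalg.eigvals(jac(z[:n], z[n]))
        resid = float(np.max(np.abs(np.asarray(f(z[:n], z[n]), dtype=float))))
        return EquilibriumPoint(
            state=z[:n].copy(),
            param=float(z[n]),
            eigenvalues=eigs,
            residual=resid,
            stability=EquilibriumPoint.classify(eigs),
        )

    z = np.append(x0, p0)
    prev = np.zeros(n + 1)
    prev[n] = float(np.sign(direction) or 1.0)
    t = _tangent(jac, jac_p, z, prev)
    points = [make_point(z)]
    status = "ok"
    step = ds
    for _ in range(max_steps):
        advanced = False
        while step >= ds_min:
            z_pred = z + step * t
            try:
                z_new = _corrector(f, jac, jac_p, z_pred, t, tol=newton_tol)
                advanced = True
                break
            except RuntimeError:
                step *= 0.5
        if not advanced:
            status = "incomplete"
            break
        t = _tangent(jac, jac_p, z_new, t)
        z = z_new
        points.append(make_point(z))
        if step < ds:
            step = min(step * 2.0, ds_max)
        if not (lo - 1e-12 <= z[n] <= hi + 1e-12):
            break
    else:
        status = "max_steps"

    branch = Branch(points=points, meta=dict(meta or {}))
    branch.meta.update(
        {
            "status": status,
            "ds": ds,
            "p_range": (lo, hi),
            "problem": {"f": f, "jac": jac, "jac_p": jac_p},
        }
    )
    return branch


# ---------------------------------------------------------------------------
# bifurcation detection and normal forms
# ---------------------------------------------------------------------------

def _fold_test(eigs: np.ndarray) -> float:
    return float(np.real(np.prod(eigs)))

def _hopf_test(eigs: np.ndarray) -> float:
    n = len(eigs)
    prod = 1.0 + 0.0j
    for i in range(n):
        for j in range(i + 1, n):
            prod *= eigs[i] + eigs[j]
    return float(np.real(prod))


def _critical_pair(eigs: np.ndarray):
    """Indices (i, j) minimizing |lambda_i + lambda_j|."""
    n = len(eigs)
    best, best_val = None, np.inf
    for i in range(n):
        for j in range(i + 1, n):
            v = abs(eigs[i] + eigs[j])
            if v < best_val:
                best, best_val = (i, j), v
    return best, best_val


def _directional_B(f, x, u, v, h=1e-4):
    """Bilinear form B(u, v) = second directional derivative of f at x.

    Polarization of central second differences; complex directions are
    allowed because f is analytic.
    """
    x = np.asarray(x, dtype=complex)

    def d2(w):
        return (np.asarray(f(x + h * w)) + np.asarray(f(x - h * w)) - 2.0 * np.asarray(f(x))) / h**2

    return 0.25 * (d2(u + v) - d2(u - v))


def _directional_C(f, x, u, v, h=1e-3, k=1e-3):
    """Trilinear form C(u, u, v) via a v-derivative of the second difference."""
    x = np.asarray(x, dtype=complex)

    def d2(base):
        return (np.asarray(f(base + h * u)) + np.asarray(f(base - h * u)) - 2.0 * np.asarray(f(base))) / h**2

    return (d2(x + k * v) - d2(x - k * v)) / (2.0 * k)


def first_lyapunov_coefficient(
    f: Callable,
    x,
    jac: Callable | None = None,
    degenerate_tol: float = 1e-10,
):
    """First Lyapunov coefficient L1 at a Hopf equilibrium of dx/dt = f(x).

    Projection method: with A q = i*omega*q, A^T p = -i*omega*p and
    <p, q> = 1 (critical eigenvector at unit norm),

        L1 = Re[ <p, C(q,q,qb)> - 2 <p, B(q, A^{-1} B(q,qb))>
                 + <p, B(qb, (2 i omega I - A)^{-1} B(q,q))> ] / (2 omega)

    with the multilinear forms B, C taken as directional finite differences
    of f (f must accept complex states).  Sign is the contract: L1 < 0 is a
    supercritical (stable-cycle) Hopf.  Returns (L1, omega, degenerate):
    ``degenerate`` flags |L1| <= degenerate_tol (possible Bautin point).

    Raises if the eigenvalue pair nearest the imaginary axis is not a
    genuine complex pair.
    """
    x = np.asarray(x, dtype=float)
    A = jac(x) if jac is not None else _fd_jac(lambda y, _p: f(y), x, 0.0)
    w, V = np.linalg.eig(A)
    cand = [i for i in range(len(w)) if np.imag(w[i]) > 1e-12]
    if not cand:
        raise ValueError("no complex eigenvalue pair: not a Hopf point")
    k = min(cand, key=lambda i: abs(np.real(w[i])))
    omega = float(np.imag(w[k]))
    q = V[:, k]
    q = q / np.linalg.norm(q)

    wl, U = np.linalg.eig(A.T)
    kl = int(np.argmin(np.abs(wl - np.conj(w[k]))))
    p = U[:, kl]
    ip = np.vdot(p, q)  # <p, q> = conj(p) . q
    if abs(ip) < 1e-12:
        raise ValueError("left/right eigenvector pairing failed")
    p = p / np.conj(ip)

    qb = np.conj(q)
    B_q_qb = _directional_B(f, x, q, qb)
    B_q_q = _directional_B(f, x, q, q)
    C_qqqb = _directional_C(f, x, q, qb)

    n = len(x)
    s1 = np.linalg.solve(A, B_q_qb)
    s2 = np.linalg.solve(2.0j * omega * np.eye(n) - A, B_q_q)
    val = np.vdot(p, C_qqqb) - 2.0 * np.vdot(p, _directional_B(f, x, q, s1)) + np.vdot(
        p, _directional_B(f, x, qb, s2)
    )
    L1 = float(np.real(val)) / (2.0 * omega)
    return L1, omega, abs(L1) <= degenerate_tol


def fold_coefficient(f: Callable, x, jac: Callable | None = None) -> float:
    """Quadratic normal-form coefficient a = <p, B(q, q)>/2 at a fold.

    q and p are the right/left null vectors of the Jacobian (eigenvalue
    nearest zero), normalized to |q| = 1, <p, q> = 1.
    """
    x = np.asarray(x, dtype=float)
    A = jac(x) if jac is not None else _fd_jac(lambda y, _p: f(y), x, 0.0)
    w, V = np.linalg.eig(A)
    k = int(np.argmin(np.abs(w)))
    q = np.real(V[:, k])
    q = q / np.linalg.norm(q)
    wl, U = np.linalg.eig(A.T)
    kl = int(np.argmin(np.abs(wl)))
    p = np.real(U[:, kl])
    p = p / (p @ q)
    B = np.real(_directional_B(f, x, q.astype(complex), q.astype(complex)))
    return 0.5 * float(p @ B)


def _solve_on_segment(f, jac, jac_p, z0, z1, s):
    """Branch point at interpolation fraction s between z0 and z1."""
    t = z1 - z0
    t = t / np.linalg.norm(t)
    z_pred = (1.0 - s) * z0 + s * z1
    return _corrector(f, jac, jac_p, z_pred, t)


def detect_bifurcations(
    branch: Branch,
    refine_tol: float = 1e-8,
    clearance: float = 1e-6,
) -> list:
    """Locate Hopf, limit and neutral-saddle points on a continued branch.

    Sign changes of the fold test function det(J) and of the Hopf test
    function prod_{i<j}(lambda_i + lambda_j) between consecutive branch
    points are bracketed and refined by bisection in the branch arclength
    down to ``refine_tol`` in the parameter.  At each refined root the
    critical pair decides the label: a complex-conjugate pair gives a Hopf
    (with L1 and omega attached); two real eigenvalues give a neutral
    saddle; a fold-test root with a near-zero real eigenvalue gives a limit
    point with its quadratic coefficient.  The refreshed list is also
    stored on ``branch.bif_points``.
    """
    prob = branch.meta.get("problem")
    if prob is None:
        raise ValueError("branch lacks its continuation problem metadata")
    f, jac, jac_p = prob["f"], prob["jac"], prob["jac_p"]
    n = len(branch.points[0].state)

    def eigs_at(z):
        return np.linalg.eigvals(jac(z[:n], z[n]))

    found = []
    for a, b in zip(branch.points[:-1], branch.points[1:]):
        za = np.append(a.state, a.param)
        zb = np.append(b.state, b.param)
        for test, label in ((_fold_test, "fold"), (_hopf_test, "hopf")):
            va, vb = test(a.eigenvalues), test(b.eigenvalues)
            if va == 0.0 or np.sign(va) == np.sign(vb):
                continue
            s_lo, s_hi, v_lo = 0.0, 1.0, va
            z_root = None
            while True:
                s_mid = 0.5 * (s_lo + s_hi)
                try:
                    z_mid = _solve_on_segment(f, jac, jac_p, za, zb, s_mid)
                except RuntimeError:
                    break
                v_mid = test(eigs_at(z_mid))
                if np.sign(v_mid) == np.sign(v_lo):
                    s_lo, v_lo = s_mid, v_mid
                else:
                    s_hi = s_mid
                z_root = z_mid
                if abs((s_hi - s_lo) * (zb[n] - za[n])) < refine_tol and abs(
                    s_hi - s_lo
                ) < 1e-3:
                    break
            if z_root is None:
                continue
            eigs = eigs_at(z_root)
            x_root, p_root = z_root[:n], float(z_root[n])
            f_at = lambda y: f(y, p_root)
            jac_at = lambda y: jac(np.real(y), p_root)
            if label == "hopf":
                (i, j), _pair_gap = _critical_pair(eigs)
                is_complex_pair = (
                    abs(np.imag(eigs[i])) > clearance
                    and abs(eigs[j] - np.conj(eigs[i])) < 1e-4 * max(1.0, abs(eigs[i]))
                )
                if is_complex_pair:
                    L1, omega, degen = first_lyapunov_coefficient(f_at, x_root, jac_at)
                    found.append(
                        BifPoint(
                            kind="Hopf", param=p_root, state=x_root,
                            eigenvalues=eigs, coefficient=L1, omega=omega,
                            degenerate=degen,
                        )
                    )
                else:
                    found.append(
                        BifPoint(
                            kind="NeutralSaddle", param=p_root, state=x_root,
                            eigenvalues=eigs,
                        )
                    )
            else:
                coef = fold_coefficient(f_at, x_root, jac_at)
                found.append(
                    BifPoint(
                        kind="LimitPoint", param=p_root, state=x_root,
                        eigenvalues=eigs, coefficient=coef,
                    )
                )
    # drop duplicates (same kind within refine tolerance)
    unique = []
    for bp in sorted(found, key=lambda b: b.param):
        if any(
            bp.kind == u.kind and abs(bp.param - u.param) < 100 * refine_tol
            for u in unique
        ):
            continue
        unique.append(bp)
    branch.bif_points = unique
    return unique


# ---------------------------------------------------------------------------
# two-parameter Hopf curve
# ---------------------------------------------------------------------------

def hopf_curve_two_param(
    f2: Callable,
    x0,
    p1_0: float,
    p2_0: float,
    *,
    omega0: float | None = None,
    p1_range: tuple = (-np.inf, np.inf),
    p2_range: tuple = (-np.inf, np.inf),
    ds: float = 0.5,
    ds_min: float = 1e-8,
    max_steps: int = 3000,
    newton_tol: float = 1e-8,
    jac_x: Callable | None = None,
    direction: int = +1,
) -> dict:
    """Continue the Hopf condition in two parameters (p1, p2).

    ``f2(x, p1, p2)`` is the vector field.  The fully extended system is
    solved: equilibrium f = 0, critical eigenpair A q = i*omega*q (real and
    imaginary parts), and the normalization <q_ref, q> = 1 against a
    reference eigenvector that is refreshed every accepted step.  A
    pseudo-arclength constraint closes the square Newton system.

    Returns a dict with arrays ``p1``, ``p2``, ``omega``, ``states``, a
    ``closed`` flag (curve returned to its start), and ``status``
    ('closed', 'range', 'incomplete', 'lost_pair' or 'max_steps').
    """
    x0 = np.asarray(x0, dtype=float)
    n = len(x0)

    if jac_x is None:

        def jac_x(x, p1, p2, eps=1e-7):
            J = np.empty((n, n))
            for i in range(n):
                step = eps * max(1.0, abs(x[i]))
                xp = x.copy(); xp[i] += step
                xm = x.copy(); xm[i] -= step
                J[:, i] = (
                    np.asarray(f2(xp, p1, p2)) - np.asarray(f2(xm, p1, p2))
                ) / (2 * step)
            return J

    # initial critical pair
    A0 = jac_x(x0, p1_0, p2_0)
    w, V = np.linalg.eig(A0)
    cand = [i for i in range(len(w)) if np.imag(w[i]) > 1e-12]
    if not cand:
        raise ValueError("no complex pair at the starting point")
    k = min(cand, key=lambda i: abs(np.real(w[i])))
    om = float(omega0) if omega0 is not None else float(np.imag(w[k]))
    q = V[:, k] / np.linalg.norm(V[:, k])
    q_ref = q.copy()

    # unknown vector u = [x (n), qr (n), qi (n), omega, p1, p2]
    def pack(x, q, om, p1, p2):
        return np.concatenate([x, np.real(q), np.imag(q), [om, p1, p2]])

    def unpack(u):
        return (
            u[:n],
            u[n : 2 * n] + 1j * u[2 * n : 3 * n],
            u[3 * n],
            u[3 * n + 1],
            u[3 * n + 2],
        )

    def F(u):
        x, q, om, p1, p2 = unpack(u)
        A = jac_x(x, p1, p2)
        Aq = A @ q
        res_eq = np.asarray(f2(x, p1, p2), dtype=float)
        res_re = np.real(Aq) + om * np.imag(q)   # A qr = -om qi
        res_im = np.imag(Aq) - om * np.real(q)   # A qi =  om qr
        norm = np.vdot(q_ref, q) - 1.0
        return np.concatenate([res_eq, res_re, res_im, [np.real(norm), np.imag(norm)]])

    m = 3 * n + 2  # equations; unknowns m + 1

    def F_jac(u, eps=1e-7):
        J = np.empty((m, m + 1))
        F0 = F(u)
        for i in range(m + 1):
            step = eps * max(1.0, abs(u[i]))
            up = u.copy(); up[i] += step
            J[:, i] = (F(up) - F0) / step
        return J, F0

    def correct(u_pred, tangent):
        u = u_pred.copy()
        for _ in range(15):
            J, F0 = F_jac(u)
            extra = tangent @ (u - u_pred)
            if np.max(np.abs(F0)) < newton_tol and abs(extra) < newton_tol:
                return u
            A = np.vstack([J, tangent])
            u = u - np.linalg.solve(A, np.append(F0, extra))
        raise RuntimeError("Hopf-curve corrector failed")

    def tangent_at(u, prev):
        J, _ = F_jac(u)
        A = np.vstack([J, prev])
        rhs = np.zeros(m + 1)
        rhs[m] = 1.0
        t = np.linalg.solve(A, rhs)
        t = t / np.linalg.norm(t)
        return t if t @ prev >= 0 else -t

    u = pack(x0, q, om, p1_0, p2_0)
    # converge the start point; `direction` orients the initial tangent
    prev = np.zeros(m + 1)
    prev[-2] = float(np.sign(direction) or 1.0)
    u = correct(u, prev)
    start_pp = np.array([u[-2], u[-1]])
    t = tangent_at(u, prev)

    p1s, p2s, oms, xs = [u[-2]], [u[-1]], [u[3 * n]], [u[:n].copy()]
    status = "max_steps"
    step = ds
    for it in range(max_steps):
        advanced = False
        while step >= ds_min:
            try:
                u_new = correct(u + step * t, t)
                advanced = True
                break
            except RuntimeError:
                step *= 0.5
        if not advanced:
            status = "incomplete"
            break
        u = u_new
        _, q, om_cur, p1, p2 = unpack(u)
        if abs(om_cur) < 1e-6:
            status = "lost_pair"  # pair collided on the real axis
            break
        q_ref = q / np.linalg.norm(q) ** 2  # keep <q_ref, q> = 1
        t = tangent_at(u, t)
        p1s.append(p1); p2s.append(p2); oms.append(om_cur); xs.append(u[:n].copy())
        if step < ds:
            step = min(step * 2.0, ds)
        if not (p1_range[0] <= p1 <= p1_range[1]) or not (
            p2_range[0] <= p2 <= p2_range[1]
        ):
            status = "range"
            break
        if it > 5 and np.linalg.norm([p1 - start_pp[0], p2 - start_pp[1]]) < 1.5 * step:
            status = "closed"
            break

    return {
        "p1": np.array(p1s),
        "p2": np.array(p2s),
        "omega": np.array(oms),
        "states": np.array(xs),
        "closed": status == "closed",
        "status": status,
    }


# ---------------------------------------------------------------------------
# orbit diagrams
# ---------------------------------------------------------------------------

def _extrema(series: np.ndarray, prominence: float = 0.05) -> np.ndarray:
    from scipy.signal import find_peaks

    hi, _ = find_peaks(series, prominence=prominence)
    lo, _ = find_peaks(-series, prominence=prominence)
    return np.sort(np.concatenate([series[hi], series[lo]]))


def _classify(series: np.ndarray, extrema: np.ndarray, tol: float) -> str:
    if len(extrema) == 0 or (np.max(series) - np.min(series)) < tol:
        return "fixed_point"
    # cluster sorted extrema by gap threshold
    gaps = np.diff(extrema)
    clusters = 1 + int(np.sum(gaps > tol))
    return "periodic" if clusters <= 2 else "bursting"


def orbit_diagram(
    model,
    param: str,
    values: Sequence[float],
    *,
    t_end: float = 400.0,
    dt: float = 0.02,
    transient_frac: float = 0.5,
    cluster_tol: float = 0.5,
    convention=None,
    I0: float = 30.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    observe: str = "S1",
) -> OrbitDiagram:
    """Brute-force bifurcation diagram: post-transient extrema vs a parameter.

    ``model`` is either a :class:`BlockParams` (single block driven by a
    constant current) or a :class:`NetworkConfig` (full chain driven at TG,
    observing the S1 potential).  ``param`` is 'I0' (constant input, pA) or
    'gNaS' (slow-sodium conductance, nS; applied to every block of a
    chain).  Per value: simulate, drop the transient, collect local extrema
    of the observed potential, classify as fixed point / periodic /
    multi-extremum bursting using the ``cluster_tol`` (mV) gap threshold.
    Deterministic throughout (constant inputs, fixed solver).  Failures at
    single values are recorded as 'missing'.
    """
    if param not in ("I0", "gNaS"):
        raise ValueError("param must be 'I0' or 'gNaS'")
    values = np.asarray(list(values), dtype=float)
    extrema_list, labels = [], []

    single = isinstance(model, BlockParams)
    for v in values:
        try:
            if single:
                params = model.with_(gNaS=v) if param == "gNaS" else model
                drive = v if param == "I0" else I0
                cfg = NetworkConfig(
                    blocks=(params,),
                    G=0.0,
                    tdcs_target=params.label,
                    convention=convention or RateConvention.CONTINUATION_CONSISTENT,
                )
                stim = Stimulus(np.array([0.0]), np.array([drive]), t_end)
                trace = simulate(cfg, stim, (0.0, t_end), dt=dt, rtol=rtol, atol=atol)
                series = trace.potentials[0]
            else:
                cfg = model
                if param == "gNaS":
                    cfg = cfg.with_(
                        blocks=tuple(b.with_(gNaS=v) for b in cfg.blocks)
                    )
                    drive = I0
                else:
                    drive = v
                stim = Stimulus(np.array([0.0]), np.array([drive]), t_end)
                trace = simulate(cfg, stim, (0.0, t_end), dt=dt, rtol=rtol, atol=atol)
                series = trace.block(observe)[0]
            tail = trim_transient(series, transient_frac)
            ext = _extrema(tail)
            extrema_list.append(ext)
            labels.append(_classify(tail, ext, cluster_tol))
        except Exception:
            extrema_list.append(np.array([]))
            labels.append("missing")

    return OrbitDiagram(
        param_name=param,
        param_values=values,
        extrema=extrema_list,
        classification=labels,
        meta={
            "t_end": t_end,
            "dt": dt,
            "transient_frac": transient_frac,
            "cluster_tol": cluster_tol,
            "model": "single_block" if single else "chain",
            "fixed_I0": I0 if param == "gNaS" else None,
        },
    )
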