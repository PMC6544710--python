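"""Single-compartment modified Hodgkin-Huxley (MHH) membrane model.

The classic four-variable Hodgkin-Huxley membrane model extended with a
slow sodium (Nav1.8) current and its two gating variables, giving a
six-variable ODE per neural block:

    Cm dE/dt = I - I_Naf - I_K - I_L - I_NaS

with

    I_Naf = gNaf * m^3 * h  * (E - ENa)   fast sodium
    I_K   = gK   * n^4      * (E - EK)    delayed-rectifier potassium
    I_L   = gL              * (E - EL)    leak
    I_NaS = gNaS * mS^3 * hS * (E - ENa)  slow (Nav1.8) sodium

Each gating variable g obeys dg/dt = alpha(E)(1-g) - beta(E) g with
voltage-dependent opening/closing rates.  Nav1.8 is the nociceptor-specific
"pain channel": its maximal conductance gNaS is the main control parameter
of the pain-network analyses built on top of this module.

Unit system (fixed throughout the package): mV, ms, pA, pF, nS.
Note pA/pF = mV/ms and nS*mV = pA, so no unit conversion factors appear.

All rate/steady-state functions are vectorized over E and accept complex
arguments (they are analytic), which the bifurcation module exploits for
complex-step derivatives and normal-form finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping

import numpy as np

__all__ = [
    "GATES",
    "BLOCK_ORDER",
    "RateConvention",
    "MHHState",
    "BlockParams",
    "CapacitanceSpec",
    "rate_constants",
    "gate_rates",
    "gate_rates_dE",
    "steady_state_gates",
    "membrane_rhs",
    "mhh_rhs",
    "ionic_currents",
    "ionic_current_balance",
    "solve_conductance_from_balance",
    "capacitance_from_permittivity",
    "default_block",
    "default_chain_blocks",
]

#: gating variables, in state-vector order (state = [E, m, h, n, mS, hS])
GATES = ("m", "h", "n", "mS", "hS")

#: the feedforward pain-pathway chain, input end first
BLOCK_ORDER = ("TG", "PAG", "thalamus", "M1", "S1")

#: vacuum permittivity, F/m (enters only through ratios)
EPS0 = 8.854e-12

#: relative permittivity per block (dimensionless, tissue values)
EPS_R = {
    "TG": 2.01e7,
    "PAG": 4.07e7,
    "thalamus": 4.07e7,
    "M1": 4.07e7,
    "S1": 4.07e7,
}


class RateConvention(str, Enum):
    """Which algebraic form of the potassium opening rate alpha_n to use.

    ``AS_PRINTED`` evaluates the literal rate expressions, under which
    alpha_n(E) = 0.006(E+45) / (1 - exp((E+45)/12)) is negative for
    E > -45 mV.  ``CONTINUATION_CONSISTENT`` (the default) flips the sign
    of the exponent in the denominator, 1 - exp(-(E+45)/12) — the classic
    HH form — which keeps alpha_n >= 0 and is the convention under which
    the reference continuation equilibria are reproducible.  The two
    variants differ in nothing else.
    """

    AS_PRINTED = "as_printed"
    CONTINUATION_CONSISTENT = "continuation_consistent"


DEFAULT_CONVENTION = RateConvention.CONTINUATION_CONSISTENT

_ALPHA_N_SING = -45.0  # removable singularity of alpha_n, mV
_SING_TOL = 1e-6  # |E+45| below this -> series limit


def _as_convention(convention) -> RateConvention:
    if convention is None:
        return DEFAULT_CONVENTION
    return RateConvention(convention)


# ---------------------------------------------------------------------------
# voltage-dependent transition rates (1/ms); E in mV
# ---------------------------------------------------------------------------

def alpha_m(E):
    E = np.asarray(E)
    return 0.115 * (1.0 + np.exp((E + 70.0) / 10.0)) / (np.exp((E + 40.0) / 42.0) + 1.0)


def beta_m(E):
    E = np.asarray(E)
    return 0.015 * (1.0 + np.exp((E + 25.0) / 8.0))


def alpha_h(E):
    E = np.asarray(E)
    return 0.012 * (1.0 + np.exp(-(E + 43.0) / 10.0))


def beta_h(E):
    E = np.asarray(E)
    return 1.32 / (1.0 + 0.2 * np.exp((E + 10.0) / 7.0))


def alpha_n(E, convention=None):
    """Potassium opening rate; removable 0/0 singularity at E = -45 mV.

    Within |E+45| < 1e-6 the analytic series limit is used (0.072/ms at
    E = -45 under the continuation-consistent convention).
    """
    convention = _as_convention(convention)
    E = np.asarray(E)
    x = E + 45.0
    near = np.abs(np.real(x)) < _SING_TOL
    safe = np.where(near, 1.0, x)
    if convention is RateConvention.CONTINUATION_CONSISTENT:
        val = 0.006 * safe / (1.0 - np.exp(-safe / 12.0))
        lim = 0.072 * (1.0 + x / 24.0)
    else:
        val = 0.006 * safe / (1.0 - np.exp(safe / 12.0))
        lim = -0.072 * (1.0 - x / 24.0)
    return np.where(near, lim, val)


def beta_n(E):
    E = np.asarray(E)
    return 0.13 * np.exp(-(E + 45.0) / 30.0)


def alpha_mS(E):
    E = np.asarray(E)
    return np.exp(0.0769 * E - 0.553)


def beta_mS(E):
    E = np.asarray(E)
    return np.exp(-0.00029 * E - 2.523)


def alpha_hS(E):
    E = np.asarray(E)
    return 0.0015 * np.exp(-(E + 40.0) / 30.0)


def beta_hS(E):
    E = np.asarray(E)
    return 0.1 / (1.0 + 0.2 * np.exp(-(E + 10.0) / 7.0))


_RATE_FUNS = {
    "m": (alpha_m, beta_m),
    "h": (alpha_h, beta_h),
    "n": (alpha_n, beta_n),
    "mS": (alpha_mS, beta_mS),
    "hS": (alpha_hS, beta_hS),
}


def rate_constants(E, gate: str, convention=None):
    """Return the (alpha, beta) transition-rate pair (1/ms) for one gate at E (mV).

    Parameters
    ----------
    E : float or array
        Membrane potential, mV.  Must be finite.
    gate : str
        One of ``m, h, n, mS, hS``.
    convention : RateConvention, optional
        Sign convention for alpha_n; ignored for the other gates.
    """
    if gate not in _RATE_FUNS:
        raise ValueError(
            f"unknown gate {gate!r}; valid gates are {', '.join(GATES)}"
        )
    if not np.all(np.isfinite(np.real(np.asarray(E)))):
        raise ValueError("membrane potential must be finite")
    af, bf = _RATE_FUNS[gate]
    alpha = af(E, convention) if gate == "n" else af(E)
    return alpha[()], bf(E)[()]


def gate_rates(E, convention=None):
    """All five (alpha, beta) rate pairs at once.

    Returns two arrays of shape ``E.shape + (5,)`` in :data:`GATES` order.
    """
    E = np.asarray(E)
    alphas = np.stack(
        [alpha_m(E), alpha_h(E), alpha_n(E, convention), alpha_mS(E), alpha_hS(E)],
        axis=-1,
    )
    betas = np.stack(
        [beta_m(E), beta_h(E), beta_n(E), beta_mS(E), beta_hS(E)], axis=-1
    )
    return alphas, betas


def gate_rates_dE(E, convention=None, h: float = 1e-20):
    """d(alpha)/dE and d(beta)/dE via complex-step differentiation.

    The rate expressions are analytic in E, so the complex step is exact to
    machine precision; used by the analytic Jacobian assembly.
    """
    E = np.asarray(E, dtype=float)
    a, b = gate_rates(E + 1j * h, convention)
    return np.imag(a) / h, np.imag(b) / h


def steady_state_gates(E, convention=None):
    """Steady-state gate vector (m, h, n, mS, hS) = alpha/(alpha+beta) at E.

    Each component is the unique fixed point of its gate ODE at clamped
    membrane potential; all components lie in (0, 1) for finite E.
    """
    if not np.all(np.isfinite(np.real(np.asarray(E)))):
        raise ValueError("membrane potential must be finite")
    a, b = gate_rates(E, convention)
    return a / (a + b)


# ---------------------------------------------------------------------------
# state and parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MHHState:
    """The six dynamical variables of one block.

    E is the membrane potential (mV); m, h gate the fast sodium current,
    n the potassium current, and mS, hS the slow (Nav1.8) sodium current.
    Gating variables are dimensionless open fractions in [0, 1].
    """

    E: float
    m: float
    h: float
    n: float
    mS: float
    hS: float

    def as_array(self) -> np.ndarray:
        return np.array([self.E, self.m, self.h, self.n, self.mS, self.hS])

    @classmethod
    def from_array(cls, y) -> "MHHState":
        y = np.asarray(y, dtype=float)
        if y.shape != (6,):
            raise ValueError("state array must have shape (6,)")
        return cls(*y)

    @classmethod
    def at_steady_state(cls, E: float, convention=None) -> "MHHState":
        """State with every gate at its steady-state value for the given E."""
        g = steady_state_gates(float(E), convention)
        return cls(float(E), *np.asarray(g, dtype=float))


@dataclass(frozen=True)
class BlockParams:
    """Biophysical parameters of one block.

    Capacitance Cm in pF; maximal conductances in nS; Nernst (reversal)
    potentials in mV.  Defaults are the committed simulation values: a
    trigeminal-ganglion block with Cm = 5 pF, gNaf = 25, gK = 20, gL = 5,
    gNaS = 100 nS, ENa = 60, EK = -75, EL = -55 mV.
    """

    label: str = "TG"
    Cm: float = 5.0
    gNaf: float = 25.0
    gK: float = 20.0
    gL: float = 5.0
    gNaS: float = 100.0
    ENa: float = 60.0
    EK: float = -75.0
    EL: float = -55.0

    def __post_init__(self):
        if not self.Cm > 0:
            raise ValueError("Cm must be positive")
        for name in ("gNaf", "gK", "gL", "gNaS"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def with_(self, **changes) -> "BlockParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class CapacitanceSpec:
    """Capacitance derivation by relative-permittivity scaling.

    The parallel-plate relation C = eps0 * epsR * A/d is used only through
    the permittivity ratio (membrane geometry A/d is common to all blocks),
    so Cm(block) = Cm_ref * epsR(block)/epsR(ref) with the trigeminal
    ganglion as the 5 pF reference.
    """

    eps0: float = EPS0
    epsR_by_block: Mapping[str, float] = field(default_factory=lambda: dict(EPS_R))
    Cm_ref: float = 5.0
    ref_block: str = "TG"

    def __post_init__(self):
        if not self.epsR_by_block.get(self.ref_block, 0.0) > 0:
            raise ValueError("reference permittivity must be positive")


def capacitance_from_permittivity(spec: CapacitanceSpec, block: str) -> float:
    """Membrane capacitance (pF) of `block` by permittivity scaling."""
    if block not in spec.epsR_by_block:
        raise KeyError(
            f"unknown block {block!r}; known blocks: {sorted(spec.epsR_by_block)}"
        )
    return spec.Cm_ref * spec.epsR_by_block[block] / spec.epsR_by_block[spec.ref_block]


def default_block(label: str = "TG", **overrides) -> BlockParams:
    """A block with the committed parameter set and permittivity-scaled Cm."""
    spec = CapacitanceSpec()
    cm = capacitance_from_permittivity(spec, label) if label in EPS_R else 5.0
    kw = dict(label=label, Cm=cm)
    kw.update(overrides)
    return BlockParams(**kw)


def default_chain_blocks(**overrides) -> tuple:
    """The five chained blocks TG -> PAG -> thalamus -> M1 -> S1."""
    return tuple(default_block(lab, **overrides) for lab in BLOCK_ORDER)


# ---------------------------------------------------------------------------
# right-hand side and current balance
# ---------------------------------------------------------------------------

def _params_arrays(params):
    """Broadcastable parameter arrays from one BlockParams or a sequence."""
    if isinstance(params, BlockParams):
        seq = [params]
        squeeze = True
    else:
        seq = list(params)
        squeeze = False
    arr = {
        name: np.array([getattr(p, name) for p in seq])
        for name in ("Cm", "gNaf", "gK", "gL", "gNaS", "ENa", "EK", "EL")
    }
    if squeeze:
        arr = {k: v[0] for k, v in arr.items()}
    return arr


def ionic_currents(y, params):
    """The four ionic currents (pA) at state(s) ``y``.

    ``y`` has shape ``(..., 6)``; returns a dict with keys
    ``Naf, K, L, NaS`` of shape ``(...)``.
    """
    y = np.asarray(y)
    p = _params_arrays(params)
    E, m, h, n, mS, hS = (y[..., i] for i in range(6))
    return {
        "Naf": p["gNaf"] * m**3 * h * (E - p["ENa"]),
        "K": p["gK"] * n**4 * (E - p["EK"]),
        "L": p["gL"] * (E - p["EL"]),
        "NaS": p["gNaS"] * mS**3 * hS * (E - p["ENa"]),
    }


def mhh_rhs(y, I, params, convention=None):
    """Vectorized MHH right-hand side.

    Parameters
    ----------
    y : array, shape (..., 6)
        State(s) ``[E, m, h, n, mS, hS]``.
    I : float or array broadcastable to ``y[..., 0]``
        Applied current, pA.
    params : BlockParams or sequence of BlockParams
        One parameter set, or one per leading row of ``y``.

    Returns dE/dt in mV/ms and gate derivatives in 1/ms, same shape as ``y``.
    """
    y = np.asarray(y)
    cur = ionic_currents(y, params)
    p = _params_arrays(params)
    E = y[..., 0]
    gates = y[..., 1:]
    a, b = gate_rates(E, convention)
    dE = (I - cur["Naf"] - cur["K"] - cur["L"] - cur["NaS"]) / p["Cm"]
    dg = a * (1.0 - gates) - b * gates
    return np.concatenate([dE[..., None], dg], axis=-1)


def membrane_rhs(state, I: float, params: BlockParams, convention=None) -> np.ndarray:
    """Time derivative of one block's state under applied current I (pA)."""
    y = state.as_array() if isinstance(state, MHHState) else np.asarray(state, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("state must be finite")
    return mhh_rhs(y, I, params, convention)


def ionic_current_balance(state, params: BlockParams) -> float:
    """Applied current (pA) that would make E stationary at the given state.

    Returns I_Naf + I_K + I_L + I_NaS; by the membrane equation this is the
    unique I for which dE/dt = 0 with the gates frozen as given.
    """
    y = state.as_array() if isinstance(state, MHHState) else np.asarray(state, dtype=float)
    cur = ionic_currents(y, params)
    total = cur["Naf"] + cur["K"] + cur["L"] + cur["NaS"]
    return total[()] if np.ndim(total) == 0 else total


_CHANNELS = ("Naf", "K", "L", "NaS")


def solve_conductance_from_balance(state, I: float, params: BlockParams, which: str) -> float:
    """The unique maximal conductance (nS) of one channel balancing I at a state.

    Solves g_which * (gating factor) * (driving force) = I - (other currents);
    substituting the result back into :func:`ionic_current_balance` reproduces
    I exactly.  Raises if the channel carries no current at this state (zero
    gating factor or zero driving force).
    """
    if which not in _CHANNELS:
        raise ValueError(f"unknown channel {which!r}; valid: {', '.join(_CHANNELS)}")
    y = state.as_array() if isinstance(state, MHHState) else np.asarray(state, dtype=float)
    E, m, h, n, mS, hS = y
    p = params
    factors = {
        "Naf": m**3 * h * (E - p.ENa),
        "K": n**4 * (E - p.EK),
        "L": (E - p.EL),
        "NaS": mS**3 * hS * (E - p.ENa),
    }
    fac = factors[which]
    if abs(fac) < 1e-300:
        raise ZeroDivisionError(
            f"channel {which} carries no current at this state "
            "(zero gating factor or zero driving force)"
        )
    conds = {"Naf": p.gNaf, "K": p.gK, "L": p.gL, "NaS": p.gNaS}
    other = sum(conds[c] * factors[c] for c in _CHANNELS if c != which)
    return (I - other) / fac
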