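"""Chained five-block pain-pathway network and trace metrics.

The pathway TG -> PAG -> thalamus -> M1 -> S1 is modelled as a strictly
feedforward chain of MHH blocks.  The external noxious stimulus (pA) drives
the trigeminal-ganglion block; every later block k receives the previous
block's membrane potential converted to a current through a scalar coupling
gain, I_k(t) = G * E_{k-1}(t) (G in nS, so mV -> pA).  Transcranial direct
current stimulation is a constant extra current added to the motor-cortex
block's input.

Trigeminal-neuralgia-like input is a telegraph process: the current
alternates between exact zero (silent intervals) and a fresh uniform draw
within user bounds, with exponentially distributed hold times.  The process
is fully determined by its seed.

Metrics (peak count, peak-to-peak, sum of squares, phase lag) operate on
post-transient windows of the uniformly sampled traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.signal import correlate, find_peaks

from .core import (
    BLOCK_ORDER,
    BlockParams,
    RateConvention,
    default_chain_blocks,
    mhh_rhs,
    steady_state_gates,
)

__all__ = [
    "StimulusSpec",
    "Stimulus",
    "make_stimulus",
    "NetworkConfig",
    "Trace",
    "SimulationError",
    "simulate",
    "trim_transient",
    "count_peaks",
    "peak_to_peak",
    "sum_squares",
    "phase_difference",
    "PhaseResult",
    "tdcs_experiment",
]


# ---------------------------------------------------------------------------
# stimulus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusSpec:
    """Specification of the external noxious-stimulus current.

    kind : 'constant' (ordinary pain), 'tn_random' (trigeminal-neuralgia-like
        telegraph signal), or 'zero'.
    amplitude : constant current, pA ('constant' kind).
    bounds : (low, high) range of the random level, pA ('tn_random'); may
        span negative to positive.
    dwell : mean hold time between re-draws, ms (exponentially distributed).
    seed : RNG seed; identical seed + parameters give a bit-identical signal.
    duration : total length of the defined signal, ms.
    """

    kind: str = "tn_random"
    amplitude: float = 30.0
    bounds: tuple = (0.0, 30.0)
    dwell: float = 25.0
    seed: int = 0
    duration: float = 500.0

    def __post_init__(self):
        if self.kind not in ("constant", "tn_random", "zero"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if self.kind == "tn_random":
            if not self.dwell > 0:
                raise ValueError("dwell must be positive for tn_random")
            lo, hi = self.bounds
            if lo > hi:
                raise ValueError(f"invalid bounds: lower {lo} > upper {hi}")


class Stimulus:
    """Piecewise-constant applied current; callable, with exposed breakpoints.

    ``breakpoints`` are segment start times (first is 0); ``levels`` the
    current on each segment.  The simulator integrates segment-by-segment so
    the discontinuities never cross an adaptive solver step.
    """

    def __init__(self, breakpoints: np.ndarray, levels: np.ndarray, duration: float):
        self.breakpoints = np.asarray(breakpoints, dtype=float)
        self.levels = np.asarray(levels, dtype=float)
        self.duration = float(duration)
        if self.breakpoints[0] != 0.0 or len(self.breakpoints) != len(self.levels):
            raise ValueError("breakpoints must start at 0 and match levels")

    def __call__(self, t):
        idx = np.searchsorted(self.breakpoints, np.asarray(t), side="right") - 1
        return self.levels[np.clip(idx, 0, len(self.levels) - 1)]


def make_stimulus(spec: StimulusSpec) -> Stimulus:
    """Build the stimulus current for a spec (deterministic given the seed)."""
    if spec.kind == "zero":
        return Stimulus(np.array([0.0]), np.array([0.0]), spec.duration)
    if spec.kind == "constant":
        return Stimulus(np.array([0.0]), np.array([spec.amplitude]), spec.duration)

    # tn_random: telegraph alternating 0 <-> Uniform(bounds), exp hold times
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.bounds
    times, levels = [0.0], []
    t, active = 0.0, False  # start silent
    while t < spec.duration:
        levels.append(rng.uniform(lo, hi) if active else 0.0)
        t += rng.exponential(spec.dwell)
        times.append(t)
        active = not active
    return Stimulus(np.array(times[:-1]), np.array(levels), spec.duration)


# ---------------------------------------------------------------------------
# network configuration and simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkConfig:
    """The feedforward five-block chain and its couplings.

    G is the scalar gain converting a block's potential (mV) into the next
    block's input current (pA); numerically 0.45 nS-equivalent, read from
    tissue conductivity.  tDCS is a constant current (pA) added to the
    input of ``tdcs_target`` (M1 by default).
    """

    blocks: tuple = field(default_factory=default_chain_blocks)
    G: float = 0.45
    tdcs_target: str = "M1"
    tdcs_amplitude: float = 0.0
    convention: RateConvention = RateConvention.CONTINUATION_CONSISTENT
    initial_E: float = -60.0

    def __post_init__(self):
        if self.G < 0:
            raise ValueError("coupling gain G must be nonnegative")
        labels = [b.label for b in self.blocks]
        if self.tdcs_target not in labels:
            raise ValueError(
                f"tdcs_target {self.tdcs_target!r} not among blocks {labels}"
            )

    @property
    def labels(self) -> tuple:
        return tuple(b.label for b in self.blocks)

    def with_(self, **changes) -> "NetworkConfig":
        return replace(self, **changes)


class SimulationError(RuntimeError):
    """Integration failure; carries the time at which the solver gave up."""

    def __init__(self, message: str, t_fail: float):
        super().__init__(f"{message} (t = {t_fail:.6g} ms)")
        self.t_fail = t_fail


@dataclass
class Trace:
    """Uniformly sampled time series of all blocks plus the applied stimulus.

    ``states`` has shape (n_blocks, 6, n_times) in state order
    [E, m, h, n, mS, hS]; ``potentials`` and ``s1`` are convenience views.
    """

    times: np.ndarray
    states: np.ndarray
    stimulus: np.ndarray
    labels: tuple
    meta: dict = field(default_factory=dict)

    @property
    def potentials(self) -> np.ndarray:
        return self.states[:, 0, :]

    @property
    def s1(self) -> np.ndarray:
        return self.states[-1, 0, :]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def block(self, label: str) -> np.ndarray:
        return self.states[self.labels.index(label)]


def default_initial_state(config: NetworkConfig) -> np.ndarray:
    """Per-block E0 with gates at their steady state for that E0."""
    y0 = np.empty((len(config.blocks), 6))
    y0[:, 0] = config.initial_E
    y0[:, 1:] = steady_state_gates(config.initial_E, config.convention)
    return y0


def simulate(
    config: NetworkConfig,
    stimulus,
    tspan: float | tuple | None = None,
    *,
    dt: float = 0.01,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    y0: np.ndarray | None = None,
) -> Trace:
    """Integrate the chained network and sample it on a uniform grid.

    Parameters
    ----------
    stimulus : Stimulus or callable t -> pA
        External current into the first block.  Piecewise-constant
        :class:`Stimulus` objects are integrated segment-by-segment.
    tspan : float or (t0, t1), optional
        Simulation window, ms; defaults to (0, stimulus.duration).
    dt : output grid step, ms (0.01 default; metrics are grid-based).
    rtol, atol : solver tolerances (1e-8 / 1e-10 defaults).
    y0 : optional initial state of shape (n_blocks, 6); defaults to
        E = initial_E with steady-state gates.

    Raises :class:`SimulationError` on solver failure or non-finite states.
    """
    n = len(config.blocks)
    if tspan is None:
        if not hasattr(stimulus, "duration"):
            raise ValueError("tspan required for a bare callable stimulus")
        tspan = (0.0, float(stimulus.duration))
    elif np.isscalar(tspan):
        tspan = (0.0, float(tspan))
    t0, t1 = float(tspan[0]), float(tspan[1])

    if y0 is None:
        y0 = default_initial_state(config)
    y = np.asarray(y0, dtype=float).reshape(n, 6).copy()

    blocks = list(config.blocks)
    tdcs_idx = config.labels.index(config.tdcs_target)
    G = config.G
    amp = config.tdcs_amplitude
    conv = config.convention

    def rhs(t, yflat, stim_val):
        Y = yflat.reshape(n, 6)
        I = np.empty(n)
        I[0] = stim_val
        I[1:] = G * Y[:-1, 0]
        I[tdcs_idx] += amp
        return mhh_rhs(Y, I, blocks, conv).ravel()

    times = t0 + dt * np.arange(int(round((t1 - t0) / dt)) + 1)
    times = times[times <= t1 + 1e-12]

    # segment boundaries: stimulus breakpoints within (t0, t1)
    if isinstance(stimulus, Stimulus):
        inner = stimulus.breakpoints[
            (stimulus.breakpoints > t0) & (stimulus.breakpoints < t1)
        ]
        edges = np.concatenate([[t0], inner, [t1]])
        seg_levels = stimulus(edges[:-1] + 0.0)
    else:
        edges = np.array([t0, t1])
        seg_levels = None

    out = np.empty((len(times), n * 6))
    out[0] = y.ravel()
    filled = 1
    for k in range(len(edges) - 1):
        a, b = edges[k], edges[k + 1]
        stim_val = (
            float(seg_levels[k]) if seg_levels is not None else float(stimulus(a))
        )
        grid = times[(times > a + 1e-12) & (times <= b + 1e-12)]
        # always integrate through the exact segment end so the next
        # segment restarts from b, not from the last grid point
        t_eval = grid if (len(grid) and abs(grid[-1] - b) < 1e-9) else np.append(grid, b)
        sol = solve_ivp(
            rhs,
            (a, b),
            y.ravel(),
            t_eval=t_eval,
            args=(stim_val,),
            method=method,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise SimulationError(
                f"solver failed: {sol.message}", sol.t[-1] if len(sol.t) else a
            )
        if not np.all(np.isfinite(sol.y)):
            raise SimulationError("non-finite state encountered", b)
        if len(grid):
            out[filled : filled + len(grid)] = sol.y.T[: len(grid)]
            filled += len(grid)
        y = sol.y[:, -1].reshape(n, 6).copy()

    # out rows are flattened (n, 6) states; rebuild as (n, 6, n_times)
    states = np.moveaxis(out[:filled].reshape(filled, n, 6), 0, -1)
    stim_series = (
        stimulus(times[:filled])
        if isinstance(stimulus, Stimulus)
        else np.asarray([float(stimulus(t)) for t in times[:filled]])
    )
    return Trace(
        times=times[:filled],
        states=states,
        stimulus=np.asarray(stim_series, dtype=float),
        labels=config.labels,
        meta={
            "rtol": rtol,
            "atol": atol,
            "dt": dt,
            "method": method,
            "tdcs_amplitude": amp,
            "G": G,
            "convention": str(conv.value),
        },
    )


# ---------------------------------------------------------------------------
# trace metrics
# ---------------------------------------------------------------------------

def trim_transient(series: np.ndarray, transient_frac: float = 0.2) -> np.ndarray:
    """Drop the leading ``transient_frac`` of a series (the startup transient)."""
    series = np.asarray(series)
    if not 0.0 <= transient_frac < 1.0:
        raise ValueError("transient_frac must be in [0, 1)")
    start = int(len(series) * transient_frac)
    return series[start:]


def count_peaks(series, prominence: float = 1.0, transient_frac: float = 0.0) -> int:
    """Number of strict local maxima with at least the given prominence (mV)."""
    x = trim_transient(series, transient_frac)
    if len(x) < 3:
        raise ValueError("series must have at least 3 samples")
    peaks, _ = find_peaks(x, prominence=prominence)
    return int(len(peaks))


def peak_to_peak(series, transient_frac: float = 0.0) -> float:
    """max - min of the post-transient series (mV); offset-invariant."""
    x = trim_transient(series, transient_frac)
    return float(np.max(x) - np.min(x))


def sum_squares(series, transient_frac: float = 0.0, remove_mean: bool = False) -> float:
    """Sum of squared post-transient samples (mV^2 * sample).

    With ``remove_mean`` the mean is subtracted first, making the metric
    invariant under a constant offset (an activity rather than level measure).
    """
    x = trim_transient(series, transient_frac)
    if remove_mean:
        x = x - np.mean(x)
    return float(np.sum(x * x))


@dataclass(frozen=True)
class PhaseResult:
    """Cross-correlation lag; ``defined`` is False for non-oscillatory input."""

    lag: float  # ms; positive means b is delayed relative to a
    defined: bool


def phase_difference(
    series_a,
    series_b,
    dt: float,
    transient_frac: float = 0.0,
    prominence: float = 1.0,
    max_lag: float | None = None,
) -> PhaseResult:
    """Lag (ms) of series_b relative to series_a maximizing cross-correlation.

    Both series must share the time grid.  If either has fewer than two
    peaks (non-oscillatory), the phase is undefined and flagged.
    """
    a = trim_transient(np.asarray(series_a, dtype=float), transient_frac)
    b = trim_transient(np.asarray(series_b, dtype=float), transient_frac)
    if a.shape != b.shape:
        raise ValueError("series must share the time grid")
    n_pk_a, _ = find_peaks(a, prominence=prominence)
    n_pk_b, _ = find_peaks(b, prominence=prominence)
    if len(n_pk_a) < 2 or len(n_pk_b) < 2:
        return PhaseResult(lag=np.nan, defined=False)
    a0, b0 = a - a.mean(), b - b.mean()
    c = correlate(b0, a0, mode="full")
    lags = np.arange(-len(a) + 1, len(a))
    if max_lag is not None:
        keep = np.abs(lags) * dt <= max_lag
        c, lags = c[keep], lags[keep]
    return PhaseResult(lag=float(lags[np.argmax(c)] * dt), defined=True)


# ---------------------------------------------------------------------------
# tDCS experiment
# ---------------------------------------------------------------------------

def tdcs_experiment(
    config: NetworkConfig,
    stimulus_spec: StimulusSpec,
    amplitudes: Sequence[float],
    *,
    transient_frac: float = 0.2,
    prominence: float = 1.0,
    remove_mean: bool = False,
    **sim_kwargs,
) -> pd.DataFrame:
    """S1 metrics of the chain for each tDCS amplitude (pA), same stimulus.

    The identical seeded stimulus drives every run; a 0-amplitude control
    row is always included.  Columns: tdcs_amplitude, sum_squares,
    peak_to_peak, n_peaks (all on the S1 potential, post-transient).
    """
    amps = list(amplitudes)
    if 0.0 not in amps:
        amps = [0.0] + amps
    stim = make_stimulus(stimulus_spec)
    rows = []
    for amp in amps:
        cfg = config.with_(tdcs_amplitude=float(amp))
        try:
            trace = simulate(cfg, stim, **sim_kwargs)
        except SimulationError as err:
            raise SimulationError(
                f"tDCS amplitude {amp} pA failed: {err}", err.t_fail
            ) from err
        s1 = trace.s1
        rows.append(
            {
                "tdcs_amplitude": float(amp),
                "sum_squares": sum_squares(
                    s1, transient_frac=transient_frac, remove_mean=remove_mean
                ),
                "peak_to_peak": peak_to_peak(s1, transient_frac=transient_frac),
                "n_peaks": count_peaks(
                    s1, prominence=prominence, transient_frac=transient_frac
                ),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["transient_frac"] = transient_frac
    df.attrs["remove_mean"] = remove_mean
    df.attrs["seed"] = stimulus_spec.seed
    return df
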