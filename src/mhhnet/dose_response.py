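"""Exponential dose-response fits and the S1-activity -> VAS pain map.

Clinical tDCS studies report pain on the 0-10 visual analog scale (VAS);
the network model reports S1 activity.  Both relations to stimulation
strength are modelled as exponentials y = a*exp(b*x) + c (2-parameter
variant fixes c = 0).  Composing the inverted S1-vs-dose fit with the
VAS-vs-dose fit maps a simulated S1 activity onto a VAS estimate.

Calibration data are scarce (typically three doses), so fits with as many
points as parameters interpolate exactly and no statistical inference is
attempted.  Queries outside the calibration dose range are flagged as
extrapolation; queries between calibration doses are flagged as
interpolation, since no measurements support intermediate doses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, curve_fit

__all__ = [
    "CalibrationPoint",
    "ExpFit",
    "VASResult",
    "fit_exponential",
    "map_s1_to_vas",
]

VAS_RANGE = (0.0, 10.0)


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration measurement: dose (mA or pA) and response."""

    dose: float
    response: float


@dataclass(frozen=True)
class ExpFit:
    """A fitted exponential y = a*exp(b*x) + c.

    ``residuals`` are observed - fitted at the calibration points;
    ``monotone`` is True when the fit is strictly monotone (a != 0, b != 0),
    with direction sign(a*b).  ``dose_hull`` is the calibration dose range,
    used for extrapolation flagging.
    """

    a: float
    b: float
    c: float
    form: str
    residuals: np.ndarray
    doses: np.ndarray
    responses: np.ndarray

    def __call__(self, x):
        return self.a * np.exp(self.b * np.asarray(x, dtype=float)) + self.c

    @property
    def monotone(self) -> bool:
        return self.a != 0.0 and self.b != 0.0

    @property
    def direction(self) -> int:
        return int(np.sign(self.a * self.b))

    @property
    def dose_hull(self) -> tuple:
        return float(np.min(self.doses)), float(np.max(self.doses))

    def invert(self, y):
        """Dose at which the fit equals y; requires a strictly monotone fit."""
        if not self.monotone:
            raise ValueError("fit is not strictly monotone; cannot invert")
        arg = (np.asarray(y, dtype=float) - self.c) / self.a
        if np.any(arg <= 0):
            raise ValueError("query outside the range of the exponential fit")
        return np.log(arg) / self.b


def _points_to_arrays(points):
    pts = [
        p if isinstance(p, CalibrationPoint) else CalibrationPoint(*p) for p in points
    ]
    x = np.array([p.dose for p in pts], dtype=float)
    y = np.array([p.response for p in pts], dtype=float)
    order = np.argsort(x)
    return x[order], y[order]


def _exact_three_point(x, y):
    """Exact (a, b, c) through three points with distinct doses.

    Eliminating a and c gives a scalar equation for b:
    (y2-y1)/(y3-y1) = (e^{b x2} - e^{b x1}) / (e^{b x3} - e^{b x1}),
    whose right side decreases monotonically from 1 (b -> -inf) to 0
    (b -> +inf), crossing the affine ratio (x2-x1)/(x3-x1) at b = 0.
    """
    x1, x2, x3 = x
    y1, y2, y3 = y
    r = (y2 - y1) / (y3 - y1)
    if not 0.0 < r < 1.0:
        raise ValueError("responses are not monotone; no exponential interpolant")
    r0 = (x2 - x1) / (x3 - x1)  # value at b = 0 (affine data)

    def g(b):
        # (e^{b x2} - e^{b x1}) / (e^{b x3} - e^{b x1}), expm1 for stability
        if b == 0.0:
            return r0 - r
        return np.expm1(b * (x2 - x1)) / np.expm1(b * (x3 - x1)) - r

    if abs(r - r0) < 1e-13:
        b = 0.0
    else:
        # root lies on the side of 0 where g has the opposite sign
        lo, hi = (0.0, 1.0) if r < r0 else (-1.0, 0.0)
        scale = 1.0 / max(abs(x3 - x1), 1e-12)
        lo, hi = lo * scale, hi * scale
        for _ in range(200):
            if np.sign(g(lo + 1e-15)) != np.sign(g(hi - 1e-15)):
                break
            lo, hi = lo * 2.0, hi * 2.0
        else:
            raise RuntimeError("failed to bracket the exponential rate")
        eps = 1e-12 * (hi - lo)
        b = brentq(g, lo + eps, hi - eps, xtol=1e-15, rtol=8.9e-16)
    if b == 0.0:
        raise ValueError("data are affine; a three-point exponential is degenerate")
    a = (y3 - y1) / (np.exp(b * x3) - np.exp(b * x1))
    c = y1 - a * np.exp(b * x1)
    return a, b, c


def fit_exponential(points: Sequence, form: str = "2-param") -> ExpFit:
    """Fit y = a*exp(b*x) (+ c for the 3-parameter form) to calibration points.

    Exact interpolation when the point count equals the parameter count
    (two points for the 2-parameter form, three for the 3-parameter form);
    nonlinear least squares otherwise.  Flat data (all responses equal)
    give b = 0 with a + c = response.  Raises on duplicate doses or a
    non-convergent fit.
    """
    if form not in ("2-param", "3-param"):
        raise ValueError("form must be '2-param' or '3-param'")
    x, y = _points_to_arrays(points)
    n_par = 2 if form == "2-param" else 3
    if len(x) < n_par:
        raise ValueError(f"{form} fit needs at least {n_par} points")
    if len(np.unique(x)) != len(x):
        raise ValueError("calibration doses must be distinct")

    def make(a, b, c):
        fit = ExpFit(
            a=float(a), b=float(b), c=float(c), form=form,
            residuals=y - (a * np.exp(b * x) + c), doses=x, responses=y,
        )
        return fit

    if np.ptp(y) == 0.0:  # flat case: b = 0, a + c = response
        return make(y[0], 0.0, 0.0)

    if form == "2-param":
        if len(x) == 2:
            if np.any(y == 0) or y[0] * y[1] < 0:
                raise ValueError(
                    "two-point exponential through zero/sign-changing responses"
                )
            b = np.log(y[1] / y[0]) / (x[1] - x[0])
            a = y[0] * np.exp(-b * x[0])
            return make(a, b, 0.0)
        # least squares; log-linear start when responses share a sign
        if np.all(y > 0) or np.all(y < 0):
            s = np.sign(y[0])
            coef = np.polyfit(x, np.log(s * y), 1)
            p0 = [s * np.exp(coef[1]), coef[0]]
        else:
            p0 = [y[0], -0.1]
        popt, _ = curve_fit(
            lambda t, a, b: a * np.exp(b * t), x, y, p0=p0, maxfev=20000
        )
        return make(popt[0], popt[1], 0.0)

    # 3-param
    if len(x) == 3:
        a, b, c = _exact_three_point(x, y)
        return make(a, b, c)
    # least squares; the offset may sit below or above the data, try both
    best = None
    for c0 in (y.min() - 0.5 * np.ptp(y), y.max() + 0.5 * np.ptp(y)):
        s = np.sign(np.mean(y - c0))
        coef = np.polyfit(x, np.log(s * (y - c0)), 1)
        try:
            popt, _ = curve_fit(
                lambda t, a, b, c: a * np.exp(b * t) + c,
                x, y, p0=[s * np.exp(coef[1]), coef[0], c0], maxfev=20000,
            )
        except RuntimeError:
            continue
        resid = float(np.sum((y - (popt[0] * np.exp(popt[1] * x) + popt[2])) ** 2))
        if best is None or resid < best[0]:
            best = (resid, popt)
    if best is None:
        raise RuntimeError("three-parameter exponential fit did not converge")
    return make(*best[1])


@dataclass(frozen=True)
class VASResult:
    """A mapped VAS estimate with its provenance flags.

    ``dose`` is the stimulation strength recovered by inverting the
    S1-vs-dose fit.  ``extrapolated`` marks queries outside the calibration
    dose range; ``interpolated`` marks doses strictly between calibration
    points (no measurement supports them).  ``clipped`` marks values cut to
    the 0-10 VAS scale.
    """

    value: float
    dose: float
    extrapolated: bool
    interpolated: bool
    clipped: bool


def map_s1_to_vas(
    s1_activity: float,
    fit_s1_vs_dose: ExpFit,
    fit_vas_vs_dose: ExpFit,
    knot_tol: float = 1e-9,
) -> VASResult:
    """Map a simulated S1 activity to a VAS pain estimate.

    Computes VAS(dose) at dose = s1_vs_dose^{-1}(s1_activity); the first
    fit must be strictly monotone.  The result is clipped to [0, 10] and
    flagged if the recovered dose lies outside (extrapolation) or strictly
    between (interpolation) the calibration doses.
    """
    if not fit_s1_vs_dose.monotone:
        raise ValueError("S1-vs-dose fit is not invertible (not strictly monotone)")
    dose = float(fit_s1_vs_dose.invert(float(s1_activity)))
    raw = float(fit_vas_vs_dose(dose))
    lo, hi = VAS_RANGE
    value = min(max(raw, lo), hi)
    d_lo, d_hi = fit_vas_vs_dose.dose_hull
    extrapolated = dose < d_lo - knot_tol or dose > d_hi + knot_tol
    at_knot = bool(np.any(np.abs(fit_vas_vs_dose.doses - dose) <= max(knot_tol, 1e-9 * max(1.0, abs(dose)))))
    return VASResult(
        value=value,
        dose=dose,
        extrapolated=extrapolated,
        interpolated=not extrapolated and not at_knot,
        clipped=value != raw,
    )
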