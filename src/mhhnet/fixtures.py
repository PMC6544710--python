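"""Deterministic fixture generation for metric and continuation tests.

Everything here is generated by code at run time (no stored binary data):
sinusoid traces with a known cycle count, seeded telegraph stimuli,
polynomial normal-form test systems with known bifurcations, and the
reference-equilibrium table in machine-readable form.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .network import StimulusSpec, make_stimulus
from .reference_states import REFERENCE_EQUILIBRIA

__all__ = [
    "sinusoid_trace",
    "telegraph_samples",
    "normal_form_hopf",
    "normal_form_fold",
    "circle_hopf_locus",
    "reference_state_table",
    "generate_fixtures",
]


def sinusoid_trace(n_cycles: int, amplitude: float = 10.0, offset: float = -50.0,
                   samples_per_cycle: int = 200, phase: float = 0.0):
    """(t, x) with exactly ``n_cycles`` full cycles; peak count equals n_cycles."""
    n = n_cycles * samples_per_cycle + 1
    t = np.linspace(0.0, float(n_cycles), n)
    x = offset + amplitude * np.sin(2.0 * np.pi * t + phase)
    return t, x


def telegraph_samples(seed: int, bounds=(0.0, 30.0), dwell: float = 25.0,
                      duration: float = 1e4, dt: float = 0.1) -> np.ndarray:
    """Uniformly sampled seeded telegraph stimulus (for distribution checks)."""
    spec = StimulusSpec(kind="tn_random", bounds=bounds, dwell=dwell,
                        seed=seed, duration=duration)
    stim = make_stimulus(spec)
    return stim(np.arange(0.0, duration, dt))


def normal_form_hopf(omega: float = 1.0, c: float = -1.0):
    """Planar Hopf normal form dz/dt = (mu + i*omega) z + c z|z|^2.

    One Hopf at mu = 0; supercritical (L1 < 0) for c < 0, subcritical for
    c > 0; computed L1 scales linearly in c.
    """

    def f(x, mu):
        r2 = x[0] * x[0] + x[1] * x[1]
        return np.array(
            [mu * x[0] - omega * x[1] + c * x[0] * r2,
             omega * x[0] + mu * x[1] + c * x[1] * r2]
        )

    return f


def normal_form_fold():
    """dx/dt = mu - x^2: one limit point at mu = 0, sheets x = +-sqrt(mu)."""

    def f(x, mu):
        return np.array([mu - x[0] * x[0]])

    return f


def circle_hopf_locus():
    """Planar system whose Hopf locus is the unit circle mu1^2 + mu2^2 = 1."""

    def f(x, p1, p2):
        s = p1 * p1 + p2 * p2 - 1.0
        return np.array([s * x[0] - x[1], x[0] + s * x[1]])

    return f


def reference_state_table() -> pd.DataFrame:
    """The six reference continuation equilibria as a DataFrame.

    Columns: label, kind, branch, E..hS (six states), param_value,
    coefficient, coefficient_name.  See :mod:`mhhnet.reference_states` for
    provenance and the documented h/hS inconsistency.
    """
    rows = []
    for r in REFERENCE_EQUILIBRIA:
        E, m, h, n, mS, hS = r.state
        rows.append(
            {
                "label": r.label, "kind": r.kind, "branch": r.branch,
                "E [mV]": E, "m [-]": m, "h [-]": h, "n [-]": n,
                "mS [-]": mS, "hS [-]": hS,
                "param_value": r.param_value,
                "coefficient": r.coefficient,
                "coefficient_name": r.coefficient_name,
            }
        )
    return pd.DataFrame(rows)


_KINDS = ("sinusoid", "telegraph", "normal_forms", "reference_states")


def generate_fixtures(kind: str, seed: int, outdir) -> list:
    """Write deterministic fixture files of one kind; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if kind == "sinusoid":
        for k in (3, 7, 11):
            t, x = sinusoid_trace(k)
            p = outdir / f"sinusoid_{k}cycles.csv"
            pd.DataFrame({"t [cycles]": t, "x [mV]": x}).to_csv(p, index=False)
            written.append(p)
    elif kind == "telegraph":
        x = telegraph_samples(seed)
        p = outdir / f"telegraph_seed{seed}.csv"
        pd.DataFrame({"I [pA]": x}).to_csv(p, index=False)
        written.append(p)
    elif kind == "normal_forms":
        p = outdir / "normal_forms.txt"
        p.write_text(
            "hopf: dz/dt = (mu + i w) z + c z|z|^2  (Hopf at mu=0, sign(L1)=sign(c))\n"
            "fold: dx/dt = mu - x^2                  (limit point at mu=0)\n"
            "circle: Hopf locus mu1^2 + mu2^2 = 1\n"
        )
        written.append(p)
    elif kind == "reference_states":
        p = outdir / "reference_equilibria.csv"
        reference_state_table().to_csv(p, index=False)
        written.append(p)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; valid: {_KINDS}")
    return written
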