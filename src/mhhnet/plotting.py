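"""Simple figure helpers for traces, orbit diagrams, branches and Hopf curves.

These regenerate the standard diagnostic views (time courses per block,
extrema-vs-parameter orbit diagrams, equilibrium branches with marked
bifurcation points, two-parameter Hopf curves).  Styling is deliberately
plain; all science lives in the data objects.
"""

from __future__ import annotations

import numpy as np


def plot_trace(trace, ax=None, blocks=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for bi, label in enumerate(trace.labels):
        if blocks is None or label in blocks:
            ax.plot(trace.times, trace.potentials[bi], label=label, lw=0.8)
    ax.set_xlabel("time [ms]")
    ax.set_ylabel("E [mV]")
    ax.legend(fontsize=8)
    return ax


def plot_orbit_diagram(diagram, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for v, ext in zip(diagram.param_values, diagram.extrema):
        if len(ext):
            ax.plot(np.full(len(ext), v), ext, "k.", ms=2)
    ax.set_xlabel(diagram.param_name)
    ax.set_ylabel("post-transient extrema [mV]")
    return ax


def plot_branch(branch, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    p = branch.params
    E = branch.states[:, 0]
    stable = np.array([pt.stability == "stable" for pt in branch.points])
    ax.plot(p[stable], E[stable], "b.", ms=2, label="stable")
    ax.plot(p[~stable], E[~stable], "r.", ms=2, label="unstable")
    for b in branch.bif_points:
        ax.plot(b.param, b.state[0], "k^" if b.kind == "Hopf" else "ks", ms=6)
        ax.annotate(b.kind, (b.param, b.state[0]), fontsize=7)
    ax.set_xlabel("parameter")
    ax.set_ylabel("equilibrium E [mV]")
    ax.legend(fontsize=8)
    return ax


def plot_hopf_curve(curve, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve["p1"], curve["p2"], "k-", lw=1)
    ax.set_xlabel("I0 [pA]")
    ax.set_ylabel("gNaS [nS]")
    return ax
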