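"""CSV/JSON writers: traces, branches, orbit diagrams, metric tables, manifests.

Every CSV written by the command-line tools is paired with a JSON manifest
(same stem, ``.manifest.json``) echoing the configuration, seed, solver
tolerances and package version needed to regenerate it.  CSV dialect:
comma-separated, '.' decimal, one header row with units in brackets.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version


def manifest_path(csv_path) -> Path:
    p = Path(csv_path)
    return p.with_suffix(p.suffix + ".manifest.json") if p.suffix != ".csv" else p.with_suffix(".manifest.json")


def write_manifest(csv_path, payload: dict) -> Path:
    """JSON sidecar with config echo, seed, tolerances and code version."""
    out = manifest_path(csv_path)
    body = {"mhhnet_version": _pkg_version, **payload}
    out.write_text(json.dumps(body, indent=2, default=_json_default) + "\n")
    return out


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "value"):  # enums
        return obj.value
    if hasattr(obj, "__dict__"):
        return obj.__dict__
    return str(obj)


def trace_frame(trace) -> pd.DataFrame:
    """One column per state variable per block, plus time and stimulus."""
    cols = {"time [ms]": trace.times, "stimulus [pA]": trace.stimulus}
    state_units = ("E [mV]", "m [-]", "h [-]", "n [-]", "mS [-]", "hS [-]")
    for bi, label in enumerate(trace.labels):
        for si, su in enumerate(state_units):
            cols[f"{label} {su}"] = trace.states[bi, si]
    return pd.DataFrame(cols)


def write_trace_csv(trace, path, manifest: dict | None = None) -> Path:
    path = Path(path)
    trace_frame(trace).to_csv(path, index=False, float_format="%.10g")
    write_manifest(path, {"kind": "trace", **(manifest or {}), "meta": trace.meta})
    return path


def write_branch_csv(branch, path, manifest: dict | None = None) -> Path:
    """Equilibrium branch: parameter, state, leading eigenvalue, stability."""
    path = Path(path)
    rows = []
    for pt in branch.points:
        lead = pt.eigenvalues[np.argmax(np.real(pt.eigenvalues))]
        rows.append(
            {
                "param": pt.param,
                "E [mV]": pt.state[0],
                "m [-]": pt.state[1],
                "h [-]": pt.state[2],
                "n [-]": pt.state[3],
                "mS [-]": pt.state[4],
                "hS [-]": pt.state[5],
                "max_re_eig [1/ms]": np.real(lead),
                "im_eig [1/ms]": np.imag(lead),
                "stability": pt.stability,
                "residual": pt.residual,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")
    meta = {k: v for k, v in branch.meta.items() if k != "problem"}
    bifs = [
        {
            "kind": b.kind,
            "param": b.param,
            "state": list(b.state),
            "coefficient": b.coefficient,
            "omega": b.omega,
        }
        for b in branch.bif_points
    ]
    write_manifest(path, {"kind": "branch", **(manifest or {}), "meta": meta, "bifurcations": bifs})
    return path


def write_orbit_csv(diagram, path, manifest: dict | None = None) -> Path:
    """Long format: one row per (parameter value, extremum)."""
    path = Path(path)
    rows = []
    for v, ext, cls in zip(diagram.param_values, diagram.extrema, diagram.classification):
        if len(ext) == 0:
            rows.append({diagram.param_name: v, "extremum [mV]": np.nan, "class": cls})
        for e in ext:
            rows.append({diagram.param_name: v, "extremum [mV]": e, "class": cls})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")
    write_manifest(path, {"kind": "orbit_diagram", **(manifest or {}), "meta": diagram.meta})
    return path


def write_table_csv(df: pd.DataFrame, path, manifest: dict | None = None) -> Path:
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.10g")
    write_manifest(path, {"kind": "table", **(manifest or {}), "attrs": dict(df.attrs)})
    return path


def write_hopf_curve_csv(curve: dict, path, manifest: dict | None = None) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "I0 [pA]": curve["p1"],
            "gNaS [nS]": curve["p2"],
            "omega [rad/ms]": curve["omega"],
        }
    ).to_csv(path, index=False, float_format="%.10g")
    write_manifest(
        path,
        {
            "kind": "hopf_curve",
            **(manifest or {}),
            "status": curve["status"],
            "closed": curve["closed"],
        },
    )
    return path
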