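"""Serializable experiment configuration (YAML or JSON).

A full experiment is described by four sections:

model:     block parameter overrides, rate convention, coupling gain G,
           tDCS target and amplitude
stimulus:  the StimulusSpec fields (kind, amplitude/bounds, dwell, seed,
           duration)
run:       integration window, output step, solver tolerances, transient
           fraction
analysis:  sweep grids, continuation ranges, tDCS amplitude lists

Re-running a serialized config reproduces all deterministic outputs
bit-identically (the stimulus is seed-generated, the solver settings are
part of the config).  ``schema_version`` guards future format changes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .core import BLOCK_ORDER, RateConvention, default_block
from .network import NetworkConfig, StimulusSpec

SCHEMA_VERSION = 1

_RUN_DEFAULTS = {
    "tspan": None,  # defaults to stimulus duration
    "dt": 0.01,
    "rtol": 1e-8,
    "atol": 1e-10,
    "transient_frac": 0.2,
}


@dataclass
class ExperimentConfig:
    """Structured, fully serializable description of one experiment."""

    model: dict = field(default_factory=dict)
    stimulus: dict = field(default_factory=dict)
    run: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION

    # -- construction -------------------------------------------------------
    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"malformed config file {path}")
        version = data.get("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"config schema version {version} not supported (expected {SCHEMA_VERSION})"
            )
        known = {"model", "stimulus", "run", "analysis", "schema_version"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        return cls(
            model=data.get("model", {}) or {},
            stimulus=data.get("stimulus", {}) or {},
            run=data.get("run", {}) or {},
            analysis=data.get("analysis", {}) or {},
        )

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path

    # -- materialization ----------------------------------------------------
    def network_config(self) -> NetworkConfig:
        m = dict(self.model)
        convention = RateConvention(m.pop("convention", RateConvention.CONTINUATION_CONSISTENT))
        G = float(m.pop("G", 0.45))
        tdcs_target = m.pop("tdcs_target", "M1")
        tdcs_amplitude = float(m.pop("tdcs_amplitude", 0.0))
        initial_E = float(m.pop("initial_E", -60.0))
        overrides = m.pop("blocks", {}) or {}
        if m:
            raise ValueError(f"unknown model keys: {sorted(m)}")
        blocks = []
        for label in BLOCK_ORDER:
            blocks.append(default_block(label, **(overrides.get(label, {}))))
        return NetworkConfig(
            blocks=tuple(blocks),
            G=G,
            tdcs_target=tdcs_target,
            tdcs_amplitude=tdcs_amplitude,
            convention=convention,
            initial_E=initial_E,
        )

    def stimulus_spec(self) -> StimulusSpec:
        s = dict(self.stimulus)
        if "bounds" in s:
            s["bounds"] = tuple(s["bounds"])
        return StimulusSpec(**s)

    def run_options(self) -> dict:
        opts = dict(_RUN_DEFAULTS)
        unknown = set(self.run) - set(opts)
        if unknown:
            raise ValueError(f"unknown run keys: {sorted(unknown)}")
        opts.update(self.run)
        return opts

    def echo(self) -> dict:
        return asdict(self)
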