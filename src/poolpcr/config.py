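"""Run configuration: YAML schema, validation, and provenance fingerprints.

The config file has four optional sections — ``simulation``, ``thermal``,
``f_anchors``, ``selection`` — each mapping onto the corresponding dataclass
defaults.  Unknown sections or keys are rejected rather than ignored, and a
short fingerprint of the fully resolved config is embedded in every output
header so results can be traced to their settings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .duplex import FFunction, ThermalParams
from .selection import DEFAULT_CAPTURE, DEFAULT_RETENTION
from .simulate import SimConfig

__all__ = ["RunConfig", "load_config"]

_SIM_KEYS = {
    "cycles", "extension_efficiency", "reequilibration_bias",
    "initial_template_conc", "primer_conc", "mode", "network_extension",
    "network_rate", "seed", "initial_copies", "normalize",
}
_THERMAL_KEYS = {"tm_full", "delta_tm_per_mismatch", "transition_width", "t_elongation"}
_SELECTION_KEYS = {"capture", "retention"}


@dataclass
class RunConfig:
    """Fully resolved run settings."""

    simulation: dict = field(default_factory=dict)
    thermal: dict = field(default_factory=dict)
    f_anchors: list | None = None
    selection: dict = field(default_factory=dict)

    def thermal_params(self) -> ThermalParams:
        return ThermalParams(**self.thermal)

    def f_function(self) -> FFunction:
        if self.f_anchors is None:
            return FFunction()
        return FFunction(tuple((float(x), float(y)) for x, y in self.f_anchors))

    def sim_config(self, **overrides) -> SimConfig:
        kwargs = dict(self.simulation)
        kwargs.update(overrides)
        kwargs.setdefault("thermal", self.thermal_params())
        kwargs.setdefault("f_function", self.f_function())
        return SimConfig(**kwargs)

    def capture(self) -> dict[str, float]:
        return {**DEFAULT_CAPTURE, **self.selection.get("capture", {})}

    def retention(self) -> dict[str, float]:
        return {**DEFAULT_RETENTION, **self.selection.get("retention", {})}

    def fingerprint(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def header_lines(self) -> list[str]:
        lines = [f"config_fingerprint={self.fingerprint()}"]
        for section in ("simulation", "thermal"):
            for key, value in sorted(getattr(self, section).items()):
                lines.append(f"{section}.{key}={value}")
        if self.f_anchors is not None:
            lines.append(f"f_anchors={self.f_anchors}")
        return lines


def _check_keys(section: str, mapping: dict, allowed: set[str]) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) in [{section}]: {sorted(unknown)}; allowed: {sorted(allowed)}"
        )


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML config; ``None`` yields all defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    _check_keys("root", raw, {"simulation", "thermal", "f_anchors", "selection"})
    simulation = raw.get("simulation", {}) or {}
    thermal = raw.get("thermal", {}) or {}
    selection = raw.get("selection", {}) or {}
    _check_keys("simulation", simulation, _SIM_KEYS)
    _check_keys("thermal", thermal, _THERMAL_KEYS)
    _check_keys("selection", selection, _SELECTION_KEYS)
    config = RunConfig(
        simulation=simulation,
        thermal=thermal,
        f_anchors=raw.get("f_anchors"),
        selection=selection,
    )
    # fail fast on invalid values
    config.sim_config()
    return config
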