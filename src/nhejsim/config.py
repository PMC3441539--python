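"""Run configuration: a YAML-serialisable record of everything a run needs.

A :class:`RunConfig` captures the model parameters, the generator of the
initial distribution, the experiment to run and the master seed, and
round-trips losslessly through YAML. Every command that writes results also
echoes its effective configuration next to them, so any published table is
regenerable from its echo alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .state_model import SimParams

__all__ = ["RunConfig", "params_from_dict", "read_config", "write_config"]

EXPERIMENTS = ("simulate", "ensemble", "sweep", "surface", "kinetics", "oracle")

_PARAM_FIELDS = {f.name: f for f in dataclasses.fields(SimParams)}


def params_from_dict(mapping: dict) -> SimParams:
    """Build SimParams from a mapping, rejecting unknown keys by name."""
    unknown = set(mapping) - set(_PARAM_FIELDS)
    if unknown:
        raise ValueError(
            f"unknown parameter key(s): {', '.join(sorted(unknown))}; "
            f"valid keys: {', '.join(sorted(_PARAM_FIELDS))}"
        )
    kwargs = {}
    for key, value in mapping.items():
        if key in ("L_min", "L_c", "n_E") and value is not None:
            value = int(value)
        kwargs[key] = value
    return SimParams(**kwargs)  # SimParams validates ranges


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one run."""

    experiment: str
    params: SimParams = field(default_factory=SimParams)
    generator: dict = field(default_factory=dict)  # {"name": ..., **kwargs}
    experiment_args: dict = field(default_factory=dict)
    n_samples: int = 1
    master_seed: Optional[int] = None
    out: Optional[str] = None

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; choose from {EXPERIMENTS}"
            )
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be >= 1, got {self.n_samples}")

    def to_dict(self) -> dict:
        return {
            "experiment": self.experiment,
            "params": dataclasses.asdict(self.params),
            "generator": dict(self.generator),
            "experiment_args": dict(self.experiment_args),
            "n_samples": self.n_samples,
            "master_seed": self.master_seed,
            "out": self.out,
        }


_TOP_KEYS = {
    "experiment", "params", "generator", "experiment_args", "n_samples",
    "master_seed", "out",
}


def read_config(path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValueError(f"{path}: malformed YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown key(s): {', '.join(sorted(unknown))}")
    if "experiment" not in raw:
        raise ValueError(f"{path}: missing required key 'experiment'")
    params = params_from_dict(raw.get("params") or {})
    return RunConfig(
        experiment=raw["experiment"],
        params=params,
        generator=raw.get("generator") or {},
        experiment_args=raw.get("experiment_args") or {},
        n_samples=int(raw.get("n_samples", 1)),
        master_seed=raw.get("master_seed"),
        out=raw.get("out"),
    )


def write_config(config: RunConfig, path) -> None:
    """Echo the effective configuration as YAML."""
    Path(path).write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True, default_flow_style=False)
    )
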