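"""Run configuration: packaged defaults merged with a user YAML file.

A run config declares input paths (per system: topology + trajectories +
ligand role declarations), the focal/pocket residue choices, all
geometric criteria, trajectory stride and frame interval, the lifetime
estimator, the linker calibration, and the seed.  Flags given on the
command line override file values.
"""

from __future__ import annotations

import copy
import hashlib
import json
from importlib import resources
from pathlib import Path

import yaml

from .contacts import ContactCriteria
from .errors import ConfigError

__all__ = ["load_defaults", "RunConfig"]


def load_defaults() -> dict:
    with resources.files("aquabridge").joinpath("defaults.yaml").open() as fh:
        return yaml.safe_load(fh)


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


class RunConfig:
    """Validated configuration for a pipeline run."""

    def __init__(self, data: dict):
        self.data = _deep_merge(load_defaults(), data or {})

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    # -- accessors ---------------------------------------------------------

    @property
    def criteria(self) -> ContactCriteria:
        c = self.data["criteria"]
        crit = ContactCriteria(
            hbond_distance_A=float(c["hbond_distance_A"]),
            hbond_angle_deg=float(c["hbond_angle_deg"]),
            salt_bridge_A=float(c["salt_bridge_A"]),
            hydrophobic_A=float(c["hydrophobic_A"]),
            dh_bond_A=float(c["dh_bond_A"]),
        )
        for name in ("hbond_distance_A", "salt_bridge_A", "hydrophobic_A"):
            if getattr(crit, name) <= 0:
                raise ConfigError(f"criteria.{name} must be positive")
        return crit

    @property
    def seed(self) -> int:
        return int(self.data.get("seed", 0))

    @property
    def systems(self) -> dict:
        return self.data.get("systems", {})

    def validate_inputs(self) -> None:
        """Check that every referenced file exists before any computation."""
        for name, spec in self.systems.items():
            topo = spec.get("topology")
            if not topo or not Path(topo).is_file():
                raise ConfigError(f"system {name!r}: topology file not found: {topo}")
            trajs = spec.get("trajectories", [])
            if not trajs:
                raise ConfigError(f"system {name!r}: no trajectories listed")
            for t in trajs:
                if not Path(t).is_file():
                    raise ConfigError(f"system {name!r}: trajectory not found: {t}")
        if int(self.data["trajectory"]["stride"]) < 1:
            raise ConfigError("trajectory.stride must be >= 1")
        if float(self.data["trajectory"]["dt_ns"]) <= 0:
            raise ConfigError("trajectory.dt_ns must be positive")
        if self.data["lifetimes"]["tau_method"] not in (
            "integral",
            "exponential_fit",
        ):
            raise ConfigError("lifetimes.tau_method must be integral|exponential_fit")

    def config_hash(self) -> str:
        blob = json.dumps(self.data, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.data, sort_keys=True)
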