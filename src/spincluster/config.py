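"""Cluster configuration files (YAML, versioned schema).

One dialect: a mapping with ``schema_version: 1``, a ``sites`` list (label +
local spin), a ``bonds`` mapping assigning every tetrahedron edge to class
2B or 4B, and a ``task`` section carrying either exchange constants or the
three-state energy gaps, plus optional CSF/projector settings and a seed.
Unknown keys are rejected with field-level messages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from pathlib import Path

import yaml

from .combinatorics import SiteSpec
from .hdvv import TETRAHEDRON_EDGES, VALID_UNITS
from .util import as_half_integer

__all__ = ["ClusterConfig", "ConfigError", "load_config", "packaged_config_path"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Schema violation in a cluster config file."""


@dataclass(frozen=True)
class ClusterConfig:
    """Validated cluster specification."""

    sites: tuple[SiteSpec, ...]
    bonds: dict[str, str]
    unit: str
    couplings: dict[str, float] | None = None      # {"j2b":, "j4b":}
    gaps: dict[str, float] | None = None           # {"singlet":, "smax":, "ground_channel":}
    seed: int = 0
    projector: dict = field(default_factory=dict)  # {"tau":, "tol":, "max_iter":}

    @property
    def site_spins(self) -> tuple[Fraction, ...]:
        return tuple(s.local_spin for s in self.sites)

    @property
    def ground_channel(self) -> Fraction | None:
        if self.gaps is None:
            return None
        return as_half_integer(self.gaps["ground_channel"], "ground_channel")


def _require_keys(section: dict, allowed: set[str], required: set[str], where: str):
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown key(s) {sorted(unknown)}")
    missing = required - set(section)
    if missing:
        raise ConfigError(f"{where}: missing required key(s) {sorted(missing)}")


def _parse_sites(raw) -> tuple[SiteSpec, ...]:
    if not isinstance(raw, list) or not raw:
        raise ConfigError("sites: must be a nonempty list")
    sites = []
    for i, entry in enumerate(raw):
        if not isinstance(entry, dict):
            raise ConfigError(f"sites[{i}]: must be a mapping")
        _require_keys(entry, {"label", "local_spin"}, {"label", "local_spin"}, f"sites[{i}]")
        try:
            spin = as_half_integer(entry["local_spin"], "local_spin")
        except ValueError as exc:
            raise ConfigError(f"sites[{i}].local_spin: {exc}") from exc
        sites.append(SiteSpec(str(entry["label"]), spin))
    labels = [s.label for s in sites]
    if len(set(labels)) != len(labels):
        raise ConfigError("sites: labels must be unique")
    return tuple(sites)


def _parse_bonds(raw, sites) -> dict[str, str]:
    if not isinstance(raw, dict):
        raise ConfigError("bonds: must be a mapping of edge -> class")
    if len(sites) != 4:
        return {str(k): str(v) for k, v in raw.items()}
    bonds = {}
    for edge, cls in raw.items():
        key = "".join(sorted(str(edge)))
        if key not in TETRAHEDRON_EDGES:
            raise ConfigError(f"bonds.{edge}: not a tetrahedron edge")
        if str(cls) not in ("2B", "4B"):
            raise ConfigError(f"bonds.{edge}: class must be 2B or 4B, got {cls!r}")
        if key in bonds:
            raise ConfigError(f"bonds.{edge}: edge assigned twice")
        bonds[key] = str(cls)
    missing = set(TETRAHEDRON_EDGES) - set(bonds)
    if missing:
        raise ConfigError(f"bonds: every edge needs a class; missing {sorted(missing)}")
    return bonds


def _parse_task(raw) -> dict:
    if not isinstance(raw, dict):
        raise ConfigError("task: must be a mapping")
    _require_keys(raw, {"unit", "couplings", "gaps", "seed", "projector"}, {"unit"}, "task")
    unit = raw["unit"]
    if unit not in VALID_UNITS:
        raise ConfigError(f"task.unit: must be one of {VALID_UNITS}, got {unit!r}")
    out = {"unit": unit, "couplings": None, "gaps": None, "seed": 0, "projector": {}}
    if "couplings" in raw:
        c = raw["couplings"]
        _require_keys(c, {"j2b", "j4b"}, {"j2b", "j4b"}, "task.couplings")
        out["couplings"] = {"j2b": float(c["j2b"]), "j4b": float(c["j4b"])}
    if "gaps" in raw:
        g = raw["gaps"]
        _require_keys(g, {"singlet", "smax", "ground_channel"},
                      {"singlet", "smax", "ground_channel"}, "task.gaps")
        out["gaps"] = {
            "singlet": float(g["singlet"]),
            "smax": float(g["smax"]),
            "ground_channel": g["ground_channel"],
        }
    if "seed" in raw:
        out["seed"] = int(raw["seed"])
    if "projector" in raw:
        p = raw["projector"]
        _require_keys(p, {"tau", "tol", "max_iter"}, set(), "task.projector")
        out["projector"] = {k: float(v) if k != "max_iter" else int(v) for k, v in p.items()}
    return out


def load_config(path) -> ClusterConfig:
    """Load and validate a cluster config; defaults filled, unknown keys
    rejected."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _require_keys(raw, {"schema_version", "sites", "bonds", "task"},
                  {"schema_version", "sites", "bonds", "task"}, str(path))
    if raw["schema_version"] != SCHEMA_VERSION:
        raise ConfigError(
            f"schema_version: expected {SCHEMA_VERSION}, got {raw['schema_version']!r}"
        )
    sites = _parse_sites(raw["sites"])
    bonds = _parse_bonds(raw["bonds"], sites)
    task = _parse_task(raw["task"])
    return ClusterConfig(sites=sites, bonds=bonds, **task)


def packaged_config_path(name: str) -> Path:
    """Path of a packaged example config (``compound1`` or ``compound2``)."""
    ref = resources.files("spincluster").joinpath(f"data/{name}.yaml")
    with resources.as_file(ref) as p:
        return Path(p)
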