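"""YAML configuration loading, validation, and run manifests.

Configs are flat YAML mappings validated against a declared field table
(name, type, range); an invalid entry raises :class:`ConfigError` naming
the offending field.  A :class:`RunManifest` snapshots the resolved
configuration, the seed expansion, the package version, and checksums of
every output file, so a run can be reproduced bit-for-bit.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import constants as c

__all__ = ["ConfigError", "load_config", "validate", "RunManifest",
           "SIMULATE_SCHEMA", "SWEEP_SCHEMA"]


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""


# field: (type, min, max, default)
SIMULATE_SCHEMA = {
    "depth_mm": (float, 1.0, 30.0, 4.0),
    "node_radius_mm": (float, 0.0, 20.0, c.NODE_RADIUS_MM),
    "voxel_mm": (float, 0.05, 2.0, c.VOXEL_SIZE_MM),
    "n_photons": (int, 1, None, 100_000),
    "n_averages": (int, 1, None, c.N_AVERAGES),
    "pO2_mmhg": (float, 0.0, None, c.PO2_OXYGENATED_MMHG),
    "nep_mpa": (float, 0.0, None, c.NEP_MPA),
    "seed": (int, 0, 2**31 - 1, 0),
    "n_delays": (int, 2, None, c.N_DELAYS),
    "delay_min_us": (float, 0.0, None, c.DELAY_MIN_US),
    "delay_max_us": (float, 0.0, None, c.DELAY_MAX_US),
    "fit_model": (str, None, None, "auto"),
}

SWEEP_SCHEMA = {
    "depths_mm": (list, None, None, list(c.SWEEP_DEPTHS_MM)),
    "pO2_levels": (list, None, None, list(c.SWEEP_PO2_MMHG)),
    "replicates": (int, 2, None, c.N_REPLICATES),
    "n_photons": (int, 1, None, 100_000),
    "n_averages": (int, 1, None, c.N_AVERAGES),
    "nep_mpa": (float, 0.0, None, c.NEP_MPA),
    "voxel_mm": (float, 0.05, 2.0, c.VOXEL_SIZE_MM),
    "seed": (int, 0, 2**31 - 1, 0),
    "fit_model": (str, None, None, "auto"),
}


def validate(raw: dict, schema: dict) -> dict:
    """Apply defaults and validate types/ranges; unknown keys are errors."""
    raw = dict(raw or {})
    out = {}
    for key in raw:
        if key not in schema:
            raise ConfigError(f"unknown config field {key!r}")
    for key, (typ, lo, hi, default) in schema.items():
        val = raw.get(key, default)
        if typ in (int, float):
            try:
                val = typ(val)
            except (TypeError, ValueError):
                raise ConfigError(
                    f"field {key!r}: expected {typ.__name__}, got {val!r}"
                ) from None
            if lo is not None and val < lo:
                raise ConfigError(f"field {key!r}: {val} below minimum {lo}")
            if hi is not None and val > hi:
                raise ConfigError(f"field {key!r}: {val} above maximum {hi}")
        elif typ is list and not isinstance(val, (list, tuple)):
            raise ConfigError(f"field {key!r}: expected a list, got {val!r}")
        elif typ is str and not isinstance(val, str):
            raise ConfigError(f"field {key!r}: expected a string, got {val!r}")
        out[key] = val
    return out


def load_config(path, schema: dict) -> dict:
    with open(path) as f:
        raw = yaml.safe_load(f)
    if raw is not None and not isinstance(raw, dict):
        raise ConfigError("config file must contain a YAML mapping")
    return validate(raw or {}, schema)


@dataclass
class RunManifest:
    """Reproducibility record of one CLI run."""

    command: str
    config: dict
    seed: int
    stage_seeds: dict = field(default_factory=dict)
    version: str = __version__
    checksums: dict = field(default_factory=dict)

    def add_output(self, path) -> None:
        p = Path(path)
        self.checksums[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()

    def write(self, path) -> None:
        with open(path, "w") as f:
            json.dump(
                {
                    "command": self.command,
                    "version": self.version,
                    "config": self.config,
                    "seed": self.seed,
                    "stage_seeds": self.stage_seeds,
                    "checksums": self.checksums,
                },
                f,
                indent=2,
                default=str,
            )
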