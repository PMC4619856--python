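"""Run configuration: schema-validated YAML/dict -> typed objects.

Every key is checked against the schema before any computation; unknown
keys are rejected with a message listing them, so typos never silently
fall back to defaults.  All randomness in a run flows from the single
top-level seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import yaml

from .geometry import FanBeamGeometry, ImageGrid
from .noise import NoiseParams
from .regularizers import RegularizerSpec

__all__ = ["ConfigError", "RunConfig", "load_config"]


class ConfigError(ValueError):
    pass


_SCHEMA = {
    "seed": None,
    "output_dir": None,
    "grid": {"nx", "ny", "pixel_size_mm"},
    "geometry": {
        "n_views",
        "n_bins",
        "source_to_iso_mm",
        "source_to_detector_mm",
        "bin_spacing_mm",
    },
    "noise": {"I0", "sigma_e2"},
    "regularizer": {"kind", "s", "smoothing_eps"},
    "solver": {
        "name",
        "beta",
        "gamma",
        "max_outer",
        "max_inner_iter",
        "max_iter",
        "inner_ncg_iters",
        "outer_tol",
        "tol",
    },
}

_DEFAULTS = {
    "seed": 0,
    "output_dir": "runs/out",
    "grid": {"nx": 128, "ny": 128, "pixel_size_mm": 1.25},
    "geometry": {
        "n_views": 180,
        "n_bins": 256,
        "source_to_iso_mm": 570.0,
        "source_to_detector_mm": 1040.0,
        "bin_spacing_mm": 1.407,
    },
    "noise": {"I0": 1e5, "sigma_e2": 11.0},
    "regularizer": {"kind": "edge_preserving", "s": 1e-3, "smoothing_eps": 1e-6},
    "solver": {"name": "alm_anad", "beta": 5e3, "gamma": None},
}


def _check_keys(section: str, given: dict, allowed: set) -> None:
    unknown = sorted(set(given) - allowed)
    if unknown:
        raise ConfigError(f"unknown keys in {section!r}: {unknown}")


@dataclass
class RunConfig:
    seed: int
    output_dir: str
    grid: ImageGrid
    geometry: FanBeamGeometry
    noise: NoiseParams
    regularizer: RegularizerSpec
    solver: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        _check_keys("config", d, set(_SCHEMA))
        merged = {}
        for key, defaults in _DEFAULTS.items():
            if isinstance(defaults, dict):
                sect = dict(defaults)
                given = d.get(key, {})
                if not isinstance(given, dict):
                    raise ConfigError(f"section {key!r} must be a mapping")
                _check_keys(key, given, _SCHEMA[key])
                sect.update(given)
                merged[key] = sect
            else:
                merged[key] = d.get(key, defaults)
        beta = merged["solver"].get("beta")
        if beta is not None and not (1e2 <= beta <= 1e4):
            warnings.warn(
                f"beta={beta:g} lies outside the empirically proper range [1e2, 1e4]",
                stacklevel=2,
            )
        reg = merged["regularizer"]
        return cls(
            seed=int(merged["seed"]),
            output_dir=str(merged["output_dir"]),
            grid=ImageGrid(**merged["grid"]),
            geometry=FanBeamGeometry(**merged["geometry"]),
            noise=NoiseParams(seed=int(merged["seed"]), **merged["noise"]),
            regularizer=RegularizerSpec(
                kind=reg["kind"],
                s=reg["s"] if reg["kind"] == "edge_preserving" else None,
                smoothing_eps=reg["smoothing_eps"],
            ),
            solver=dict(merged["solver"]),
            raw=merged,
        )

    def snapshot_yaml(self) -> str:
        return yaml.safe_dump(self.raw, sort_keys=True)


def load_config(path) -> RunConfig:
    with open(path) as f:
        d = yaml.safe_load(f) or {}
    if not isinstance(d, dict):
        raise ConfigError("config file must contain a mapping")
    return RunConfig.from_dict(d)
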