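"""Run configuration: defaults, config-file parsing, and overrides.

Configuration is a flat mapping with keys namespaced by pipeline stage
(``movie.*``, ``segment.*``, ``track.*``, ``classify.*``, ``simulate.*``),
stored as YAML.  Precedence: CLI flags > config file > defaults.  Unknown
keys are rejected so typos fail loudly, and every default is printable
(``atcq show-config``).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import yaml

from .classification import ClassifierConfig
from .segmentation import SegmentationParams
from .simulate import MovieSpec
from .tracking import TrackingParams

__all__ = [
    "ConfigError",
    "RunConfig",
    "default_config",
    "load_config",
    "merge_config",
]


class ConfigError(ValueError):
    """Invalid or unknown configuration keys."""


_NAMESPACES = {
    "movie": MovieSpec,
    "segment": SegmentationParams,
    "track": TrackingParams,
    "classify": ClassifierConfig,
}

#: simulate-stage keys that are not dataclass-backed
_SIMULATE_KEYS = {"profile", "n_founders", "seed"}


def default_config() -> dict[str, dict[str, Any]]:
    """Nested mapping of every tunable default, by namespace."""
    out: dict[str, dict[str, Any]] = {}
    for ns, cls in _NAMESPACES.items():
        d = {}
        for f in dataclasses.fields(cls):
            v = f.default
            if v is dataclasses.MISSING:
                v = f.default_factory() if f.default_factory is not dataclasses.MISSING else None
            d[f.name] = v
        out[ns] = d
    out["simulate"] = {"profile": "pc3_hotel", "n_founders": 50, "seed": 0}
    return out


def _validate(cfg: dict) -> None:
    for ns, vals in cfg.items():
        if ns == "simulate":
            unknown = set(vals) - _SIMULATE_KEYS
            if unknown:
                raise ConfigError(f"unknown simulate keys: {sorted(unknown)}")
            continue
        cls = _NAMESPACES.get(ns)
        if cls is None:
            raise ConfigError(
                f"unknown config namespace {ns!r}; known: {sorted(_NAMESPACES) + ['simulate']}"
            )
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(vals) - known
        if unknown:
            raise ConfigError(f"unknown {ns} keys: {sorted(unknown)}")


def load_config(path) -> dict:
    """Load a YAML config file.  Accepts nested (``segment: {noise_k: 3}``)
    or flat dotted (``segment.noise_k: 3``) keys."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    nested: dict[str, dict] = {}
    for k, v in data.items():
        if isinstance(v, dict):
            nested.setdefault(k, {}).update(v)
        elif "." in str(k):
            ns, key = str(k).split(".", 1)
            nested.setdefault(ns, {})[key] = v
        else:
            raise ConfigError(f"top-level key {k!r} is neither a namespace nor dotted")
    _validate(nested)
    return nested


def merge_config(*layers: dict) -> dict:
    """Merge config layers, later layers winning."""
    out: dict[str, dict] = {}
    for layer in layers:
        for ns, vals in (layer or {}).items():
            out.setdefault(ns, {}).update(vals)
    _validate(out)
    return out


def _build(cls, overrides: dict):
    kwargs = {}
    for k, v in (overrides or {}).items():
        if isinstance(v, list):
            v = tuple(v)
        kwargs[k] = v
    return cls(**kwargs)


@dataclasses.dataclass
class RunConfig:
    """Resolved parameter objects for one run."""

    movie: MovieSpec
    segment: SegmentationParams
    track: TrackingParams
    classify: ClassifierConfig
    profile: str = "pc3_hotel"
    n_founders: int = 50
    seed: int = 0

    @staticmethod
    def from_layers(*layers: dict) -> "RunConfig":
        cfg = merge_config(*layers)
        sim = cfg.get("simulate", {})
        return RunConfig(
            movie=_build(MovieSpec, cfg.get("movie", {})),
            segment=_build(SegmentationParams, cfg.get("segment", {})),
            track=_build(TrackingParams, cfg.get("track", {})),
            classify=_build(ClassifierConfig, cfg.get("classify", {})),
            profile=sim.get("profile", "pc3_hotel"),
            n_founders=int(sim.get("n_founders", 50)),
            seed=int(sim.get("seed", 0)),
        )
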