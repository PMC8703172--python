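"""Kinetic condition profiles for the dual-reporter cell-cycle simulator.

A :class:`KineticProfile` bundles the stochastic parameters of the
reporter/cell-cycle state machine for one experimental condition: onset
delays of the G0 (mVenus-p27K-) and G1 (mCherry-hCdt1) reporters after
cytokinesis, dwell-time distributions in the Venus/Cherry double-positive
(DP) decision window, phase durations up to the next division, daughter-pair
fate probabilities and the asynchrony-delta distribution.

Profiles ship as YAML files under ``atcq/profiles`` and every field can be
overridden by key.  Named profiles:

``t3t3_fullserum``
    NIH/3T3 fibroblasts under full serum; Venus onset 2-4 h after
    cytokinesis, Cherry 3-4 h later, transient DP dwell 5-10 h, 64.4 % of
    post-mitotic cells exceed the 14 h spontaneous-G0 threshold, 30 % of
    daughter pairs decide asynchronously with G1-entry deltas of 1-15 h.
``pc3_hotel`` / ``pc3_plate``
    PC3 prostate cancer cells imaged in the microfluidic "cell hotel"
    (27.5 % spontaneous G0) or on a plate (20 %); onset ~2 h + ~2 h, Venus
    degraded within ~4 h of Cherry onset in cycling cells, asynchronous
    daughter deltas of 1-6 h in 30 % of pairs.
``t3t3_lowserum``
    serum starvation: nearly all trajectories collapse into prolonged G0.
``serumfree_from_g1`` / ``serumfree_from_sgm``
    serum-free cohorts seeded from sorted G1 (Cherry-only) or S/G2/M
    (double-negative) cells; 90 % / 85 % of cells are double positive at the
    72 h snapshot, the remainder modelled as reporter-silent.
``pc3_gas6`` / ``pc3_tgfb2`` / ``pc3_gmcsf``
    dormancy-signal treatment presets (directional shifts of the control
    ``pc3_hotel`` parameters).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "Distribution",
    "KineticProfile",
    "ProfileError",
    "available_profiles",
    "get_profile",
    "load_profile_file",
    "marginal_spontaneous_prob",
]

#: Dwell threshold (hours) above which a double-positive phase is scored as
#: spontaneous G0.  Strict inequality: "prolonged beyond 14 h".
SPONTANEOUS_THRESHOLD_H = 14.0


class ProfileError(ValueError):
    """Raised for invalid profile configuration (probabilities out of range,
    malformed distributions, unknown keys)."""


# ---------------------------------------------------------------------------
# distributions
# ---------------------------------------------------------------------------

_DIST_KINDS = ("constant", "uniform", "shifted_expon", "lognorm")


@dataclass(frozen=True)
class Distribution:
    """A small serialisable family of nonnegative duration distributions.

    Backed by frozen scipy distributions; ``kind`` is one of

    - ``constant``: point mass at ``a``
    - ``uniform``: uniform on ``[a, b]``
    - ``shifted_expon``: ``a + Exponential(scale=b)``
    - ``lognorm``: log-normal with log-mean ``a`` and log-sigma ``b``
    """

    kind: str
    a: float
    b: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _DIST_KINDS:
            raise ProfileError(f"unknown distribution kind {self.kind!r}")
        lo = self.support()[0]
        if lo < 0:
            raise ProfileError(f"distribution {self} has negative support")

    def _frozen(self):
        if self.kind == "uniform":
            return stats.uniform(loc=self.a, scale=self.b - self.a)
        if self.kind == "shifted_expon":
            return stats.expon(loc=self.a, scale=self.b)
        if self.kind == "lognorm":
            return stats.lognorm(s=self.b, scale=float(np.exp(self.a)))
        raise AssertionError(self.kind)

    def rvs(self, rng: np.random.Generator, size=None):
        # sampled straight from the Generator: called once per event per
        # cell, so avoiding scipy's frozen-object overhead matters
        if self.kind == "constant":
            return self.a if size is None else np.full(size, self.a)
        if self.kind == "uniform":
            return rng.uniform(self.a, self.b, size=size)
        if self.kind == "shifted_expon":
            return self.a + rng.exponential(self.b, size=size)
        if self.kind == "lognorm":
            return rng.lognormal(self.a, self.b, size=size)
        raise AssertionError(self.kind)

    def mean(self) -> float:
        if self.kind == "constant":
            return self.a
        return float(self._frozen().mean())

    def support(self) -> tuple[float, float]:
        if self.kind == "constant":
            return (self.a, self.a)
        if self.kind == "uniform":
            return (self.a, self.b)
        return (self.a if self.kind == "shifted_expon" else 0.0, np.inf)

    def to_dict(self) -> dict:
        d = {"dist": self.kind, "a": float(self.a)}
        if self.kind != "constant":
            d["b"] = float(self.b)
        return d

    @staticmethod
    def from_spec(spec) -> "Distribution":
        """Build from a YAML-friendly spec: number -> constant, mapping with
        ``dist`` plus parameters (``low``/``high`` accepted for uniform,
        ``shift``/``scale`` for shifted_expon)."""
        if isinstance(spec, Distribution):
            return spec
        if isinstance(spec, (int, float)):
            return Distribution("constant", float(spec))
        if not isinstance(spec, dict):
            raise ProfileError(f"cannot parse distribution spec {spec!r}")
        d = dict(spec)
        kind = d.pop("dist")
        if kind == "uniform":
            a = d.pop("low", d.pop("a", None))
            b = d.pop("high", d.pop("b", None))
        elif kind == "shifted_expon":
            a = d.pop("shift", d.pop("a", 0.0))
            b = d.pop("scale", d.pop("b", None))
        elif kind == "lognorm":
            a = d.pop("mu", d.pop("a", None))
            b = d.pop("sigma", d.pop("b", None))
        elif kind == "constant":
            a = d.pop("value", d.pop("a", None))
            b = 0.0
        else:
            raise ProfileError(f"unknown distribution kind {kind!r}")
        if d:
            raise ProfileError(f"unknown distribution keys {sorted(d)}")
        if a is None or b is None:
            raise ProfileError(f"incomplete distribution spec {spec!r}")
        return Distribution(kind, float(a), float(b))


# ---------------------------------------------------------------------------
# profile
# ---------------------------------------------------------------------------

_FOUNDER_MODES = ("asynchronous", "g1_arrest", "sgm_arrest")


@dataclass(frozen=True)
class KineticProfile:
    """Per-condition stochastic parameters of the reporter state machine.

    Durations are hours, positions pixels.  ``pair_fate_probs`` is
    ``(p_sync_g0, p_sync_g1, p_async)`` for daughter pairs at each division;
    ``p_spontaneous_g0`` is the per-cell marginal probability that a
    post-mitotic cell's DP dwell exceeds the 14 h spontaneous threshold.
    """

    name: str
    venus_onset_delay: Distribution
    cherry_onset_delay: Distribution
    dp_dwell_transient: Distribution
    dp_dwell_prolonged: Distribution
    g1_duration: Distribution
    sgm_duration: Distribution
    pair_fate_probs: tuple[float, float, float]
    async_delta: Distribution
    p_spontaneous_g0: float
    venus_rise_h: float = 3.0
    cherry_rise_h: float = 3.0
    venus_fall_h: float = 3.0
    cherry_fall_h: float = 3.0
    sync_delta_max_h: float = 0.5
    p_reporter_silent: float = 0.0
    motility_sigma: float = 0.4
    founder_mode: str = "asynchronous"
    founder_spread_h: float = 30.0
    founder_p_g0: Optional[float] = None
    spontaneous_threshold_h: float = SPONTANEOUS_THRESHOLD_H
    transient_threshold_h: float = 4.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        p = self.pair_fate_probs
        if len(p) != 3 or any(not (0.0 <= x <= 1.0) for x in p):
            raise ProfileError(f"pair_fate_probs out of range: {p}")
        if abs(sum(p) - 1.0) > 1e-9:
            raise ProfileError(f"pair_fate_probs must sum to 1, got {sum(p)!r}")
        for nm in ("p_spontaneous_g0", "p_reporter_silent"):
            v = getattr(self, nm)
            if not (0.0 <= v <= 1.0):
                raise ProfileError(f"{nm}={v} out of [0, 1]")
        if self.founder_p_g0 is not None and not (0.0 <= self.founder_p_g0 <= 1.0):
            raise ProfileError(f"founder_p_g0={self.founder_p_g0} out of [0, 1]")
        if self.founder_mode not in _FOUNDER_MODES:
            raise ProfileError(f"unknown founder_mode {self.founder_mode!r}")
        if self.dp_dwell_prolonged.support()[0] <= self.spontaneous_threshold_h:
            raise ProfileError(
                "dp_dwell_prolonged support must exceed the spontaneous threshold"
            )
        if self.dp_dwell_transient.support()[1] > self.spontaneous_threshold_h:
            raise ProfileError(
                "dp_dwell_transient support must stay below the spontaneous threshold"
            )
        for nm in (
            "venus_rise_h",
            "cherry_rise_h",
            "venus_fall_h",
            "cherry_fall_h",
            "motility_sigma",
            "founder_spread_h",
        ):
            if getattr(self, nm) < 0:
                raise ProfileError(f"{nm} must be nonnegative")

    # convenience -----------------------------------------------------------
    @property
    def p_sync_g0(self) -> float:
        return self.pair_fate_probs[0]

    @property
    def p_sync_g1(self) -> float:
        return self.pair_fate_probs[1]

    @property
    def p_async(self) -> float:
        return self.pair_fate_probs[2]

    def with_overrides(self, **kwargs) -> "KineticProfile":
        """Return a copy with fields replaced (distribution specs accepted)."""
        parsed = {}
        for k, v in kwargs.items():
            if k in _DIST_FIELDS:
                parsed[k] = Distribution.from_spec(v)
            elif k == "pair_fate_probs":
                parsed[k] = _parse_pair_probs(v)
            else:
                parsed[k] = v
        return replace(self, **parsed)

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "founder_mode": self.founder_mode,
            "founder_spread_h": self.founder_spread_h,
            "p_spontaneous_g0": self.p_spontaneous_g0,
            "p_reporter_silent": self.p_reporter_silent,
            "pair_fate_probs": {
                "sync_g0": self.pair_fate_probs[0],
                "sync_g1": self.pair_fate_probs[1],
                "async": self.pair_fate_probs[2],
            },
            "motility_sigma": self.motility_sigma,
            "sync_delta_max_h": self.sync_delta_max_h,
            "spontaneous_threshold_h": self.spontaneous_threshold_h,
            "transient_threshold_h": self.transient_threshold_h,
        }
        if self.founder_p_g0 is not None:
            d["founder_p_g0"] = self.founder_p_g0
        for nm in ("venus_rise_h", "cherry_rise_h", "venus_fall_h", "cherry_fall_h"):
            d[nm] = getattr(self, nm)
        for nm in _DIST_FIELDS:
            d[nm] = getattr(self, nm).to_dict()
        return d


_DIST_FIELDS = (
    "venus_onset_delay",
    "cherry_onset_delay",
    "dp_dwell_transient",
    "dp_dwell_prolonged",
    "g1_duration",
    "sgm_duration",
    "async_delta",
)


def _parse_pair_probs(v) -> tuple[float, float, float]:
    if isinstance(v, dict):
        try:
            return (float(v["sync_g0"]), float(v["sync_g1"]), float(v["async"]))
        except KeyError as e:  # pragma: no cover - config error path
            raise ProfileError(f"pair_fate_probs missing key {e}") from None
    t = tuple(float(x) for x in v)
    if len(t) != 3:
        raise ProfileError("pair_fate_probs needs 3 components")
    return t


def profile_from_dict(d: dict) -> KineticProfile:
    d = dict(d)
    kwargs = {}
    known = set(KineticProfile.__dataclass_fields__)
    for k in list(d):
        if k not in known:
            raise ProfileError(f"unknown profile key {k!r}")
    for k, v in d.items():
        if k in _DIST_FIELDS:
            kwargs[k] = Distribution.from_spec(v)
        elif k == "pair_fate_probs":
            kwargs[k] = _parse_pair_probs(v)
        else:
            kwargs[k] = v
    return KineticProfile(**kwargs)


# ---------------------------------------------------------------------------
# calibration helper
# ---------------------------------------------------------------------------


def marginal_spontaneous_prob(
    pair_fate_probs,
    dp_dwell_transient: Distribution,
    async_delta: Distribution,
    threshold_h: float = SPONTANEOUS_THRESHOLD_H,
    n_mc: int = 200_000,
) -> float:
    """Per-cell marginal probability of a DP dwell beyond ``threshold_h``.

    Under the pair-fate generative model a randomly chosen daughter is
    spontaneous with probability ``p_sync_g0 + 0.5 * p_async * q`` where
    ``q = P(d + delta > threshold)`` for a transient dwell ``d`` and an
    asynchrony delta.  ``q`` is evaluated by a fixed-seed Monte-Carlo sum, so
    the result is deterministic.
    """
    p_sync_g0, _, p_async = pair_fate_probs
    rng = np.random.default_rng(1234567)
    d = np.asarray(dp_dwell_transient.rvs(rng, size=n_mc), dtype=float)
    delta = np.asarray(async_delta.rvs(rng, size=n_mc), dtype=float)
    q = float(np.mean(d + delta > threshold_h))
    return p_sync_g0 + 0.5 * p_async * q


# ---------------------------------------------------------------------------
# shipped profiles
# ---------------------------------------------------------------------------


def _profile_dir():
    return importlib.resources.files("atcq") / "profiles"


def available_profiles() -> list[str]:
    """Names of the YAML profiles shipped with the package."""
    return sorted(p.name[:-5] for p in _profile_dir().iterdir() if p.name.endswith(".yaml"))


def load_profile_file(path) -> KineticProfile:
    """Load a profile from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ProfileError(f"profile file {path} does not contain a mapping")
    return profile_from_dict(data)


def get_profile(name: str, **overrides) -> KineticProfile:
    """Load a shipped profile by name (or a YAML path), with overrides.

    Raises :class:`ProfileError` if the name is unknown.
    """
    p = Path(str(name))
    if p.suffix in (".yaml", ".yml") and p.exists():
        prof = load_profile_file(p)
    else:
        res = _profile_dir() / f"{name}.yaml"
        if not res.is_file():
            raise ProfileError(
                f"unknown profile {name!r}; available: {', '.join(available_profiles())}"
            )
        prof = profile_from_dict(yaml.safe_load(res.read_text()))
    if overrides:
        prof = prof.with_overrides(**overrides)
    return prof
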