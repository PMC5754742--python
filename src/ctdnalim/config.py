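"""YAML/dict configuration loading for all model parameter sets.

A config file is a YAML mapping with optional sections ``allometry``,
``plasma``, ``anchor``, ``detection``, ``screening`` and ``cohort``; any
omitted key falls back to the model default.  Example::

    plasma:
      cfdna_ng_per_ml: 5.0
      plasma_ml_per_draw: 4.0
    anchor:
      mass_mg: 10000
      fraction: 0.001
    cohort:
      n: 100000
      prevalence: 0.01
      size_distribution: {kind: point, value: 27}
      seed: 42
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping

import yaml

from .abundance import PlasmaParams, ShedAnchor
from .detection import DetectionParams
from .geometry import AllometryConstants
from .screening import ScreeningParams
from .simulate import CohortConfig, SizeDistribution

__all__ = [
    "load_config",
    "allometry_from",
    "plasma_from",
    "anchor_from",
    "detection_from",
    "screening_from",
    "cohort_from",
]


def load_config(path: str | Path | None) -> dict:
    """Load a YAML config file; ``None`` gives an all-defaults config."""
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, Mapping):
        raise ValueError("config file must contain a mapping at top level")
    return dict(cfg)


def _section(cfg: Mapping[str, Any], name: str) -> dict:
    sec = cfg.get(name) or {}
    if not isinstance(sec, Mapping):
        raise ValueError(f"config section {name!r} must be a mapping")
    return dict(sec)


def allometry_from(cfg: Mapping[str, Any]) -> AllometryConstants:
    return AllometryConstants(**_section(cfg, "allometry"))


def plasma_from(cfg: Mapping[str, Any]) -> PlasmaParams:
    return PlasmaParams(**_section(cfg, "plasma"))


def anchor_from(cfg: Mapping[str, Any]) -> ShedAnchor:
    sec = _section(cfg, "anchor")
    kwargs = {}
    if "mass_mg" in sec:
        kwargs["anchor_mass_mg"] = sec["mass_mg"]
    if "fraction" in sec:
        kwargs["anchor_fraction"] = sec["fraction"]
    return ShedAnchor(**kwargs)


def detection_from(cfg: Mapping[str, Any]) -> DetectionParams:
    return DetectionParams(**_section(cfg, "detection"))


def screening_from(cfg: Mapping[str, Any]) -> ScreeningParams:
    return ScreeningParams(**_section(cfg, "screening"))


def cohort_from(cfg: Mapping[str, Any], seed: int | None = None) -> CohortConfig:
    """Build a :class:`CohortConfig`; ``seed`` overrides the config's seed."""
    sec = _section(cfg, "cohort")
    dist_spec = dict(sec.pop("size_distribution", {"kind": "point", "value": 27.0}))
    kind = dist_spec.pop("kind")
    dist = SizeDistribution(kind=kind, params=dist_spec)
    if seed is not None:
        sec["seed"] = seed
    if "seed" not in sec:
        raise ValueError("cohort config requires a seed")
    return CohortConfig(size_distribution=dist, **sec)
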