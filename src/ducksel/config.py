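"""Run configuration: thresholds, season windows, priors, MCMC settings.

Loaded from YAML with strict key checking — a typo in a config key aborts
before any computation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import yaml

from .dcm import McmcConfig, Priors
from .movement import DEFAULT_SEASON_WINDOWS


@dataclass
class Thresholds:
    fine_max_km: float = 0.33
    relocation_min_km: float = 25.0
    buffer_km: float = 0.4
    spacing_km: float = 2.12
    radius_km: float | None = None  # None => 97.5th local step-length quantile
    quantile: float = 0.975
    corr_threshold: float = 0.8
    delta_dic: float = 5.0
    rhat: float = 1.1
    censor_days: float = 4.0
    diel_margin_min: float = 30.0

    def __post_init__(self) -> None:
        for name in ("fine_max_km", "relocation_min_km", "buffer_km", "spacing_km",
                     "quantile", "corr_threshold", "delta_dic", "rhat"):
            if getattr(self, name) is not None and getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


@dataclass
class Paths:
    fixes: str | None = None
    raster: str | None = None
    catalog: str | None = None
    ownership: str | None = None
    feed_sites: str | None = None
    output_dir: str = "results"


@dataclass
class RunConfig:
    paths: Paths = field(default_factory=Paths)
    thresholds: Thresholds = field(default_factory=Thresholds)
    priors: Priors = field(default_factory=Priors)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    season_windows: tuple = DEFAULT_SEASON_WINDOWS
    solar_lat: float = 42.4
    solar_lon: float = -82.5
    models: tuple[str, ...] = ("random", "risk", "resource", "full")
    seed: int = 0

    def digest(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, (date,)):
                return o.isoformat()
            if isinstance(o, tuple):
                return list(o)
            raise TypeError(type(o))

        blob = json.dumps(dataclasses.asdict(self), default=enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _build(cls, payload: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise ValueError(f"unknown config key(s) in {where}: {sorted(unknown)}")
    return cls(**payload)


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    top = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - top
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    kwargs = {}
    for section, cls in (("paths", Paths), ("thresholds", Thresholds),
                         ("priors", Priors), ("mcmc", McmcConfig)):
        if section in raw:
            kwargs[section] = _build(cls, raw[section] or {}, section)
    if "season_windows" in raw:
        kwargs["season_windows"] = tuple(
            (date.fromisoformat(str(a)), date.fromisoformat(str(b)), lab)
            for a, b, lab in raw["season_windows"]
        )
    for key in ("solar_lat", "solar_lon", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    if "models" in raw:
        kwargs["models"] = tuple(raw["models"])
    return RunConfig(**kwargs)
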