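"""Run configuration: YAML/JSON loading, validation, and hashing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping, Optional, Union

import yaml

from .design import DesignConfig
from .exceptions import ConfigurationError
from .observer import CovariateEffect, PopulationConfig


@dataclass
class AnalysisConfig:
    """Knobs of the analysis stages."""

    bin_width: float = 0.5
    min_trials: int = 5
    n_boot: int = 2000
    ci_method: str = "bootstrap"
    delta_granularity: str = "stimulus"
    cutoff_scopes: tuple = ("pooled", "by_emotion")

    def validate(self) -> None:
        if self.bin_width <= 0:
            raise ConfigurationError("analysis.bin_width must be > 0")
        if self.min_trials < 3:
            raise ConfigurationError("analysis.min_trials must be >= 3")
        if self.n_boot < 0:
            raise ConfigurationError("analysis.n_boot must be >= 0")
        if self.ci_method not in ("bootstrap", "asymptotic"):
            raise ConfigurationError(f"unknown analysis.ci_method {self.ci_method!r}")
        if self.delta_granularity not in ("stimulus", "condition"):
            raise ConfigurationError(
                f"unknown analysis.delta_granularity {self.delta_granularity!r}"
            )
        for scope in self.cutoff_scopes:
            if scope not in ("pooled", "by_emotion"):
                raise ConfigurationError(f"unknown cutoff scope {scope!r}")


@dataclass
class RunConfig:
    """Top-level configuration: design, population, analysis blocks and a seed."""

    design: DesignConfig = field(default_factory=DesignConfig)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0

    def validate(self) -> None:
        self.design.validate()
        self.population.validate()
        self.analysis.validate()


def _build(cls, data: Mapping[str, Any], block: str):
    known = {f.name for f in fields(cls)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigurationError(f"unknown keys in block {block!r}: {unknown}")
    return cls(**data)


def _coerce_population(data: dict) -> PopulationConfig:
    data = dict(data)
    if "covariate_effects" in data:
        effects = []
        for item in data["covariate_effects"]:
            if not isinstance(item, Mapping):
                raise ConfigurationError("population.covariate_effects entries must be mappings")
            effects.append(_build(CovariateEffect, item, "population.covariate_effects"))
        data["covariate_effects"] = effects
    if "acc_means" in data and isinstance(data["acc_means"], Mapping):
        data["acc_means"] = {
            tuple(k.split("/")) if isinstance(k, str) else tuple(k): v
            for k, v in data["acc_means"].items()
        }
    if "covariate_dists" in data and isinstance(data["covariate_dists"], Mapping):
        data["covariate_dists"] = {k: tuple(v) for k, v in data["covariate_dists"].items()}
    if "sim_tau_bounds" in data:
        data["sim_tau_bounds"] = tuple(data["sim_tau_bounds"])
    return _build(PopulationConfig, data, "population")


def load_run_config(
    source: Union[str, Path, Mapping[str, Any]],
    required_blocks: tuple = ("population",),
) -> RunConfig:
    """Load and validate a run configuration from YAML/JSON (or a mapping).

    Missing required blocks and unknown keys raise
    :class:`~emofusion.exceptions.ConfigurationError` naming the block.
    """
    if isinstance(source, Mapping):
        raw: Any = dict(source)
    else:
        path = Path(source)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        text = path.read_text()
        if path.suffix.lower() == ".json":
            raw = json.loads(text)
        else:
            raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")

    known_blocks = {"design", "population", "analysis", "seed"}
    unknown = sorted(set(raw) - known_blocks)
    if unknown:
        raise ConfigurationError(f"unknown top-level config blocks: {unknown}")
    for block in required_blocks:
        if block not in raw:
            raise ConfigurationError(f"config is missing the required block {block!r}")

    design_raw = raw.get("design") or {}
    if "face_actors" in design_raw:
        design_raw = dict(design_raw)
        design_raw["face_actors"] = {g: list(a) for g, a in design_raw["face_actors"].items()}
    if "voice_actors" in design_raw:
        design_raw = dict(design_raw)
        design_raw["voice_actors"] = {g: list(a) for g, a in design_raw["voice_actors"].items()}

    cfg = RunConfig(
        design=_build(DesignConfig, design_raw, "design"),
        population=_coerce_population(raw.get("population") or {}),
        analysis=_build(AnalysisConfig, raw.get("analysis") or {}, "analysis"),
        seed=int(raw.get("seed", 0)),
    )
    cfg.validate()
    return cfg


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, Mapping):
        return {
            "/".join(k) if isinstance(k, tuple) else str(k): _jsonable(v)
            for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))
        }
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (int, float, str, bool)) or obj is None:
        return obj
    return str(obj)


def config_hash(config: RunConfig) -> str:
    """SHA-256 over the canonical JSON form of every analyzed field."""
    payload = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()
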