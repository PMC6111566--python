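"""Pipeline configuration: one YAML file is the source of truth.

Sections mirror the stage configs (preprocess, features, selection,
classification) plus the simulation block used when no input records are
given.  Unknown keys are rejected so typos fail loudly; the parse/validate
round trip is lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields as dc_fields

import yaml

from .preprocess import PreprocessConfig
from .timedomain import TimeDomainConfig
from .nonlinear import EntropyConfig, HiguchiConfig, PRSAConfig

__all__ = ["PipelineConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    pass


def _build(cls, d: dict, section: str):
    known = {f.name for f in dc_fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown keys in section {section!r}: {sorted(unknown)}")
    try:
        return cls(**d)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section {section!r}: {exc}") from exc


@dataclass
class FeatureConfigSection:
    baseline_window_s: float = 240.0
    psd_method: str = "welch"
    time: TimeDomainConfig = field(default_factory=TimeDomainConfig)
    entropy: EntropyConfig = field(default_factory=EntropyConfig)
    higuchi: HiguchiConfig = field(default_factory=HiguchiConfig)
    prsa: PRSAConfig = field(default_factory=PRSAConfig)


@dataclass
class SimulateSection:
    n_normal: int = 8
    n_pathological: int = 8
    effect: float = 2.0
    duration_s: float = 1500.0


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureConfigSection = field(default_factory=FeatureConfigSection)
    simulate: SimulateSection = field(default_factory=SimulateSection)
    selection: str = "none"  # none | st | auc | pca
    classifier: str = "adaboost"  # dt | svm | adaboost
    normalization: str = "none"  # none | ga | minmax
    folds: int = 10
    seed: int = 20180820
    paper_mode: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        known = {f.name for f in dc_fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
        out = {}
        if "preprocess" in d:
            out["preprocess"] = _build(PreprocessConfig, d.pop("preprocess"), "preprocess")
        if "features" in d:
            fd = dict(d.pop("features"))
            for key, sub in (("time", TimeDomainConfig), ("entropy", EntropyConfig),
                             ("higuchi", HiguchiConfig), ("prsa", PRSAConfig)):
                if key in fd:
                    fd[key] = _build(sub, fd[key], f"features.{key}")
            out["features"] = _build(FeatureConfigSection, fd, "features")
        if "simulate" in d:
            out["simulate"] = _build(SimulateSection, d.pop("simulate"), "simulate")
        out.update(d)
        cfg = _build(cls, out, "pipeline")
        if cfg.selection not in ("none", "st", "auc", "pca"):
            raise ConfigError(f"unknown selection {cfg.selection!r}")
        if cfg.classifier not in ("dt", "svm", "adaboost"):
            raise ConfigError(f"unknown classifier {cfg.classifier!r}")
        if cfg.normalization not in ("none", "ga", "minmax"):
            raise ConfigError(f"unknown normalization {cfg.normalization!r}")
        return cfg


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is not None and not isinstance(data, dict):
        raise ConfigError("config file must hold a mapping")
    return PipelineConfig.from_dict(data or {})
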