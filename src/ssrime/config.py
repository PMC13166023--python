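"""Pipeline configuration: one JSON-serializable object bundling the
preprocessing, decomposition, feature, generator, and evaluation settings,
with a single seed driving every source of randomness."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .decomposition import CeemdanParams
from .features import SSRIMEParams
from .io import PreprocessConfig
from .synthetic import SynthConfig

__all__ = ["EvalSettings", "PipelineConfig", "load_config", "save_config"]


@dataclass
class EvalSettings:
    classifier: str = "svm"
    n_folds: int = 10
    n_repeats: int = 10
    tuned: bool = False


@dataclass
class PipelineConfig:
    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)
    ceemdan: CeemdanParams = field(default_factory=CeemdanParams)
    ssrime: SSRIMEParams = field(default_factory=SSRIMEParams)
    synth: SynthConfig = field(default_factory=SynthConfig)
    evaluation: EvalSettings = field(default_factory=EvalSettings)
    seed: int = 0
    log_level: str = "INFO"

    def with_seed(self, seed: int) -> "PipelineConfig":
        cfg = dataclasses.replace(self, seed=seed)
        cfg.ceemdan = dataclasses.replace(cfg.ceemdan, seed=seed)
        cfg.synth = dataclasses.replace(cfg.synth, seed=seed)
        return cfg


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return list(obj)
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def _coerce(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(json.dumps(_to_jsonable(config), indent=2, sort_keys=True))


def load_config(path) -> PipelineConfig:
    data = json.loads(Path(path).read_text())
    return config_from_dict(data)


def config_from_dict(data: dict) -> PipelineConfig:
    return PipelineConfig(
        preprocessing=_coerce(PreprocessConfig, data.get("preprocessing", {})),
        ceemdan=_coerce(CeemdanParams, data.get("ceemdan", {})),
        ssrime=_coerce(SSRIMEParams, data.get("ssrime", {})),
        synth=_coerce(SynthConfig, data.get("synth", {})),
        evaluation=_coerce(EvalSettings, data.get("evaluation", {})),
        seed=int(data.get("seed", 0)),
        log_level=str(data.get("log_level", "INFO")),
    )
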