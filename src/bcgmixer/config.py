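"""Schema-validated pipeline configuration.

One nested config object drives every stage; all defaults equal the study
protocol (30-s windows, Hann 128 / overlap 15/16 / NFFT 128, 224x224x3
images, patch 5 / hidden 32 / depth 7, SGDM batch 64 / 7 epochs / lr 0.001,
10-fold CV, 50-min trim).  Unknown keys are rejected so typos cannot
silently fall back to defaults.  A frozen ``paper_defaults`` profile ships
with the package.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .convmixer import TrainConfig
from .signals import SyntheticParams
from .spectrogram import SpectrogramConfig

__all__ = ["ConfigError", "PipelineConfig", "load_config"]


class ConfigError(ValueError):
    """Invalid or unknown configuration key/value."""


def _build(cls, d: dict, path: str):
    if not isinstance(d, dict):
        raise ConfigError(f"section {path!r} must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section {path!r}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        if isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    try:
        return cls(**kwargs)
    except ValueError as exc:
        raise ConfigError(f"section {path!r}: {exc}") from exc


@dataclass
class SyntheticSection:
    n_hpt: int = 61
    n_nrt: int = 67
    duration_min: float = 50.0
    fs: float = 100.0
    params: SyntheticParams = field(default_factory=SyntheticParams)

    def __post_init__(self) -> None:
        if self.n_hpt < 1 or self.n_nrt < 1:
            raise ValueError("class counts must be >= 1")
        if self.duration_min <= 0 or self.fs <= 0:
            raise ValueError("duration_min and fs must be positive")


@dataclass
class PreprocessingSection:
    filter: str = "canonical"  # "canonical" (fixed constants) or "designed"
    designed_order: int = 4
    designed_f_low: float = 1.0
    designed_f_high: float = 49.0
    designed_stop_atten_db: float = 40.0
    zero_phase: bool = False
    window_s: float = 30.0

    def __post_init__(self) -> None:
        if self.filter not in ("canonical", "designed"):
            raise ValueError("filter must be 'canonical' or 'designed'")
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")


@dataclass
class ModelSection:
    patch_size: int = 5
    hidden_dim: int = 32
    depth: int = 7
    depthwise_kernel: int = 5
    prose_residual: bool = False


@dataclass
class EvaluationSection:
    k: int = 10
    grouping: str = "image_level"  # the reported protocol; "subject_level" avoids leakage

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.grouping not in ("image_level", "subject_level"):
            raise ValueError("grouping must be 'image_level' or 'subject_level'")


@dataclass
class ProtocolSection:
    trim_minutes: float = 50.0  # every recording trimmed to its first 50 min

    def __post_init__(self) -> None:
        if self.trim_minutes <= 0:
            raise ValueError("trim_minutes must be positive")


@dataclass
class PipelineConfig:
    synthetic: SyntheticSection = field(default_factory=SyntheticSection)
    preprocessing: PreprocessingSection = field(default_factory=PreprocessingSection)
    spectrogram: SpectrogramConfig = field(default_factory=SpectrogramConfig)
    model: ModelSection = field(default_factory=ModelSection)
    training: TrainConfig = field(default_factory=TrainConfig)
    evaluation: EvaluationSection = field(default_factory=EvaluationSection)
    protocol: ProtocolSection = field(default_factory=ProtocolSection)
    seed: int = 0
    out_dir: str = "runs"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        if not isinstance(d, dict):
            raise ConfigError("config root must be a mapping")
        sections = {
            "synthetic": SyntheticSection,
            "preprocessing": PreprocessingSection,
            "spectrogram": SpectrogramConfig,
            "model": ModelSection,
            "training": TrainConfig,
            "evaluation": EvaluationSection,
            "protocol": ProtocolSection,
        }
        unknown = set(d) - set(sections) - {"seed", "out_dir"}
        if unknown:
            raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")
        kwargs = {}
        for name, sec_cls in sections.items():
            if name in d:
                sub = dict(d[name]) if d[name] is not None else {}
                if name == "synthetic" and "params" in sub:
                    sub["params"] = _build(SyntheticParams, sub["params"], "synthetic.params")
                kwargs[name] = _build(sec_cls, sub, name)
        if "seed" in d:
            kwargs["seed"] = int(d["seed"])
        if "out_dir" in d:
            kwargs["out_dir"] = str(d["out_dir"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return json.loads(json.dumps(dataclasses.asdict(self), default=str))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(spec: str | Path | None) -> PipelineConfig:
    """Load a config from a YAML path or a named packaged profile.

    ``None`` and ``"paper_defaults"`` both give the frozen default profile.
    """
    if spec is None:
        return PipelineConfig()
    p = Path(spec)
    if p.exists():
        return PipelineConfig.from_yaml(p)
    candidate = resources.files("bcgmixer").joinpath(f"profiles/{spec}.yaml")
    if candidate.is_file():
        with resources.as_file(candidate) as real:
            return PipelineConfig.from_yaml(real)
    raise ConfigError(f"config {spec!r} is neither a file nor a known profile")
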