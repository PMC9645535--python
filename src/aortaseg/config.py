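"""Run configuration and provenance.

A run config is a YAML mapping with a fixed set of known sections; unknown
keys are rejected with a listing (typos should fail loudly, not silently
fall back to defaults).  Every artifact directory gets a provenance file
recording the config hash, seeds and package version, so runs are
reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .nn.unet import ModelConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "write_provenance"]

_KNOWN_KEYS = {"paths", "preprocessing", "augmentation", "models", "folds", "seed"}
_KNOWN_MODEL_STAGES = {"roi_contrast", "roi_noncontrast", "thoracic",
                       "abdominal", "noncontrast"}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    paths: dict = field(default_factory=dict)
    preprocessing: dict = field(default_factory=lambda: {
        "isotropic_mm": 1.0, "roi_factor": 3.2, "window": [-100.0, 400.0]})
    augmentation: dict = field(default_factory=lambda: {"ratio": 10, "seed": 0})
    models: dict = field(default_factory=dict)  # stage name -> ModelConfig
    folds: dict = field(default_factory=lambda: {
        "k": 3, "n_train": 50, "n_test": 25, "seed": 0})
    seed: int = 0

    def model_config(self, stage: str) -> ModelConfig:
        return self.models.get(stage, ModelConfig())

    def to_dict(self) -> dict:
        d = asdict(self)
        d["models"] = {k: asdict(v) for k, v in self.models.items()}
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = sorted(set(raw) - _KNOWN_KEYS)
    if unknown:
        raise ConfigError(f"{path}: unknown config keys: {', '.join(unknown)}")
    models = {}
    for stage, kw in (raw.get("models") or {}).items():
        if stage not in _KNOWN_MODEL_STAGES:
            raise ConfigError(f"{path}: unknown model stage '{stage}' "
                              f"(known: {sorted(_KNOWN_MODEL_STAGES)})")
        try:
            models[stage] = ModelConfig(**kw)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: invalid model config '{stage}': {exc}")
    cfg = RunConfig(seed=int(raw.get("seed", 0)), models=models)
    for key in ("paths", "preprocessing", "augmentation", "folds"):
        if key in raw:
            getattr(cfg, key).update(raw[key])
    return cfg


def write_provenance(out_dir: str | Path, cfg: RunConfig | None = None,
                     **extra) -> Path:
    """Drop a provenance JSON next to a run's artifacts."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {"package": "aortaseg", "version": __version__, **extra}
    if cfg is not None:
        record["config_hash"] = cfg.digest()
        record["seed"] = cfg.seed
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(record, indent=2, sort_keys=True))
    return path
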