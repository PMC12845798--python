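"""Run configuration: a versioned YAML schema tying all stages together.

Unknown keys are rejected (fail fast), and the resolved configuration is
written back into every run directory so runs are reproducible from their
artifacts alone.
"""

from __future__ import annotations

import dataclasses
import pathlib
from dataclasses import dataclass, field

import yaml

from .preprocessing import PreprocessConfig

__all__ = ["RunConfig", "load_config", "save_config"]

SCHEMA_VERSION = 1

_SIM_KEYS = {"n_subjects", "duration_s", "hr_min", "hr_max", "fs",
             "hrv_sd", "hr_drift_amp_bpm", "hr_drift_hz"}
_MODEL_KEYS = {
    "filters_per_kernel", "pool_size", "tcn_channels", "tcn_kernel",
    "lstm_hidden", "attn_heads", "d_fusion", "dropout_p", "use_tcn",
    "use_bilstm", "use_mhsa", "use_dynamic_fusion", "modality",
    "hr_min", "hr_max", "delta", "learning_rate", "lr_factor",
    "lr_patience", "early_patience", "max_epochs", "batch_size",
    "validation_fraction",
}
_PRE_KEYS = {f.name for f in dataclasses.fields(PreprocessConfig)}


@dataclass
class RunConfig:
    seed: int = 0
    simulate: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION

    def preprocess_config(self) -> PreprocessConfig:
        return PreprocessConfig(**self.preprocess)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(
            f"unknown keys in config section {section!r}: {sorted(unknown)}")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    _check_keys("<root>", raw, {"seed", "simulate", "preprocess", "model",
                                "paths", "schema_version"})
    version = raw.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version {version}")
    cfg = RunConfig(
        seed=int(raw.get("seed", 0)),
        simulate=dict(raw.get("simulate") or {}),
        preprocess=dict(raw.get("preprocess") or {}),
        model=dict(raw.get("model") or {}),
        paths=dict(raw.get("paths") or {}),
        schema_version=version)
    _check_keys("simulate", cfg.simulate, _SIM_KEYS)
    _check_keys("preprocess", cfg.preprocess, _PRE_KEYS)
    _check_keys("model", cfg.model, _MODEL_KEYS)
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
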