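"""Layered run configuration: defaults <- preset <- config file <- flags.

A :class:`RunConfig` bundles the model configuration with the data options
and run bookkeeping (seed, output directory).  It serializes to YAML so a run
directory always carries the fully resolved configuration, and a saved
manifest reproduces the run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .model import ModelConfig

#: Dataset presets carrying the published dropout/epoch settings.
PRESETS: dict[str, dict] = {
    "oneil": {"dropout": 0.2, "epochs": 200},
    "cloud": {"dropout": 0.2, "epochs": 200},
    "almanac": {"dropout": 0.0, "epochs": 500},
    # compact configuration for interactive desk use
    "desk": {"dropout": 0.0, "epochs": 100, "d": 16, "latent": 32,
             "modality_hidden": 64, "pred_hidden": (128,), "mol_layers": (32, 32)},
}


@dataclass
class RunConfig:
    """Resolved configuration of one command invocation."""

    model: ModelConfig = field(default_factory=ModelConfig)
    metric: str = "loewe"
    folds: int = 10
    aggregate: str = "mean"   # replicate handling in the synergy table
    out_dir: str | None = None

    def to_yaml(self, path) -> None:
        data = asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        model_data = dict(data.pop("model", {}))
        for key in ("mol_layers", "pred_hidden"):
            if key in model_data and model_data[key] is not None:
                model_data[key] = tuple(model_data[key])
        cfg = cls(model=ModelConfig(**model_data))
        known = {f.name for f in fields(cls)} - {"model"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys {sorted(unknown)}")
        return replace(cfg, **data)

    def apply_preset(self, preset: str) -> "RunConfig":
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
        settings = dict(PRESETS[preset])
        for key in ("mol_layers", "pred_hidden"):
            if key in settings:
                settings[key] = tuple(settings[key])
        return replace(self, model=replace(self.model, **settings))

    def override_model(self, **kwargs) -> "RunConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, model=replace(self.model, **kwargs)) if kwargs else self


def resolve_config(preset: str | None = None, config_file=None,
                   **flag_overrides) -> RunConfig:
    """Merge the configuration layers in increasing precedence."""
    cfg = RunConfig()
    if preset:
        cfg = cfg.apply_preset(preset)
    if config_file:
        file_cfg = RunConfig.from_yaml(config_file)
        # file settings override preset for every explicitly present key
        raw = yaml.safe_load(Path(config_file).read_text()) or {}
        model_keys = raw.get("model", {})
        cfg = cfg.override_model(**{k: getattr(file_cfg.model, k) for k in model_keys})
        for key in raw:
            if key != "model":
                cfg = replace(cfg, **{key: getattr(file_cfg, key)})
    top = {k: v for k, v in flag_overrides.items()
           if k in {f.name for f in fields(RunConfig)} and v is not None}
    model_flags = {k: v for k, v in flag_overrides.items() if k not in top}
    cfg = replace(cfg, **top)
    return cfg.override_model(**model_flags)
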