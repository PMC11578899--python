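"""Pipeline configuration: one human-editable YAML file, explicit seeds.

Every source of randomness in the pipeline flows from named seeds (session
generation, cohort sampling, measurement noise), so identical config files
give identical outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .cohort import CouplingConfig
from .glm import GlmConfig
from .task import SessionConfig

__all__ = ["PipelineConfig", "ConfigError", "load_config", "default_config_yaml"]


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs."""

    seed: int = 0
    n_per_group: int | None = None  # None -> the 178-subject preset
    session: SessionConfig = field(default_factory=SessionConfig)
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    glm: GlmConfig = field(default_factory=GlmConfig)
    estimate_via: str = "noise"  # "noise" or "glm"
    include_np_interactions: bool = True
    out_dir: str = "pipeline_out"

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {"session": SessionConfig, "coupling": CouplingConfig, "glm": GlmConfig}
_TOP_KEYS = {
    "seed",
    "n_per_group",
    "estimate_via",
    "include_np_interactions",
    "out_dir",
} | set(_SECTIONS)

_REQUIRED = {"seed"}


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a pipeline config; unknown or missing keys are errors."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown config keys: {sorted(unknown)}")
    missing = _REQUIRED - set(raw)
    if missing:
        raise ConfigError(f"{path}: missing required config key: {sorted(missing)}")
    kwargs: dict = {}
    for key, value in raw.items():
        if key in _SECTIONS:
            cls = _SECTIONS[key]
            if not isinstance(value, dict):
                raise ConfigError(f"{path}: section '{key}' must be a mapping")
            valid = set(cls.__dataclass_fields__)
            bad = set(value) - valid
            if bad:
                raise ConfigError(f"{path}: unknown keys in '{key}': {sorted(bad)}")
            try:
                kwargs[key] = cls(**{
                    k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
                })
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"{path}: invalid '{key}' section: {exc}") from exc
        else:
            kwargs[key] = value
    try:
        return PipelineConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def default_config_yaml() -> str:
    """A commented template config."""
    return """\
# noveltytask pipeline configuration
seed: 0                # master seed; session/cohort/noise streams derive from it
n_per_group: null      # null -> the 178-subject preset (45/45/44/44)
estimate_via: noise    # 'noise' (Gaussian estimation error) or 'glm' (full BOLD sim + OLS)
include_np_interactions: true
out_dir: pipeline_out
session:
  n_novel: 40
  lifetime_min: 5
  lifetime_max: 9
coupling:
  mean_explore: 1.2
  mean_nonexplore: 0.8
  sd: 1.0
  noise_sd: 0.5
  d_neglect_explore: 0.0
glm:
  tr: 2.5
  noise_sd: 1.0
"""
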