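"""YAML run configuration: validation, defaults, and round-tripping.

A single config file drives every CLI command.  It mirrors the three
ingredient objects::

    model:            # ModelParams fields (all optional, defaults apply)
      mu_E: 6.0
      ...
    scenario:         # FishingScenario for `solve` / `simulate`
      F0: 0.1
      gamma: 0.0
    run:
      n_replicates: 10000
      seed: 0
      gamma_grid: {start: -0.3, stop: 0.3, step: 0.05}
      F0_grid: {start: 0.0, stop: 0.4, step: 0.05}
      sweep_gammas: [-0.3, 0.0, 0.3]

Validation failures are reported field by field.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .params import FishingScenario, ModelParams

__all__ = ["GridSpec", "RunSettings", "RunConfig", "ConfigError",
           "load_config", "default_config_yaml"]


class ConfigError(ValueError):
    """Invalid configuration; ``errors`` lists per-field messages."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  " + "\n  ".join(errors))


class GridSpec(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")
    start: float
    stop: float
    step: float = Field(gt=0)

    def values(self) -> np.ndarray:
        return np.round(np.arange(self.start, self.stop + 1e-9, self.step), 10)


class RunSettings(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")
    n_replicates: int = Field(10_000, ge=1)
    seed: int = Field(0, ge=0)
    gamma_grid: GridSpec = GridSpec(start=-0.3, stop=0.3, step=0.05)
    F0_grid: GridSpec = GridSpec(start=0.0, stop=0.4, step=0.05)
    sweep_gammas: tuple[float, ...] = (-0.3, 0.0, 0.3)


class RunConfig(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")
    model: ModelParams = ModelParams()
    scenario: FishingScenario = FishingScenario(F0=0.1, gamma=0.0)
    run: RunSettings = RunSettings()


def _format_errors(exc: ValidationError) -> list[str]:
    msgs = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        msgs.append(f"{loc}: {err['msg']}")
    return msgs


def load_config(path: str | Path, overrides: dict | None = None) -> RunConfig:
    """Parse and validate a YAML config; raise :class:`ConfigError` on failure.

    ``overrides`` maps dotted field paths (e.g. ``"scenario.gamma"``) to
    replacement scalar values; they are applied before validation.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(["<root>: config must be a mapping"])
    for dotted, value in (overrides or {}).items():
        node = raw
        *parents, leaf = dotted.split(".")
        for p in parents:
            node = node.setdefault(p, {})
        node[leaf] = value
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(_format_errors(exc)) from None


def default_config_yaml() -> str:
    """A fully explicit config snapshot of every default, YAML-formatted."""
    cfg = RunConfig()
    return yaml.safe_dump(cfg.model_dump(), sort_keys=False)
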