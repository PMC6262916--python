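"""Model parameters and harvest scenarios.

All tunable quantities of the life-history model live in two validated,
immutable containers:

* :class:`ModelParams` — biology and numerics: bioenergetics, the five
  mortality components, the stochastic forage environment, and the state /
  choice grids used by the dynamic-programming solver.
* :class:`FishingScenario` — one harvest regime, i.e. a baseline fishing
  mortality ``F0`` and the behavioral gear-selectivity coefficient ``gamma``.

Both round-trip through plain dictionaries (and hence YAML) so that every
run is fully self-documenting.
"""

from __future__ import annotations

import hashlib
import json
from typing import Any

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["ModelParams", "FishingScenario"]


class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    def to_dict(self) -> dict[str, Any]:
        return self.model_dump()

    def content_hash(self) -> str:
        """Stable hex digest of the full parameter set (for run manifests)."""
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class ModelParams(_Frozen):
    """Every parameter of the bioenergetic / mortality / environment model.

    Defaults are the cod-like parameterization used throughout: a long-lived
    demersal fish whose net energy intake is ``R = h·W^b − b0·(W+G)^a`` with
    food intake ``h = φ·E``, and whose total mortality is the sum of a fixed
    background rate, size-dependent predation, a cost of carrying gonads,
    a foraging-activity exposure term, and fishing.
    """

    # --- bioenergetics -----------------------------------------------------
    a: float = Field(0.7, gt=0, le=1, description="metabolic cost exponent")
    b: float = Field(0.7, gt=0, le=1, description="intake mass exponent")
    b0: float = Field(0.3, ge=0, description="metabolic cost coefficient")
    k: float = Field(0.95, gt=0, description="length-weight coefficient, g/cm^3")

    # --- mortality ---------------------------------------------------------
    c: float = Field(1.2, ge=0, description="size-dependent mortality coefficient, 1/yr")
    d: float = Field(-0.75, lt=0, description="size-dependent mortality exponent")
    p: float = Field(2.0, gt=0, description="cost-of-carrying-gonads exponent")
    q_ref: float = Field(0.2, gt=0, lt=1,
                         description="GSI at which reproduction mortality equals size mortality")
    phi_ref: float = Field(1.4, gt=0, description="reference foraging strategy φ̄ (= θ)")
    M_fixed: float = Field(0.05, ge=0, description="fixed background mortality, 1/yr")
    phi_foraging_mort_exp: float = Field(
        2.0, gt=0, description="exponent x of the foraging-exposure mortality (φ/φ̄)^x·M_size")

    # --- forage environment ------------------------------------------------
    mu_E: float = Field(6.0, description="stationary mean of annual food availability E")
    sigma_E: float = Field(2.5, gt=0, description="stationary SD of E")
    rho_E: float = Field(0.5, ge=-1.0, lt=1.0, description="lag-1 autocorrelation of E")
    n_E_nodes: int = Field(9, ge=1, description="Markov discretization size for E")
    E_span_sd: float = Field(3.0, gt=0, description="node span in stationary SDs about mu_E")

    # --- horizon and integration -------------------------------------------
    T_max: int = Field(30, ge=2, description="maximum age, years")
    n_substeps: int = Field(24, ge=1, description="within-year Euler substeps")

    # --- state / choice grids ----------------------------------------------
    L_min: float = Field(1.0, gt=0, description="smallest length node, cm")
    L_max: float = Field(130.0, gt=0, description="largest length node, cm")
    L_step: float = Field(1.0, gt=0, description="length node spacing, cm")
    phi_max: float = Field(4.0, gt=0, description="largest foraging choice")
    phi_step: float = Field(0.05, gt=0, description="foraging choice spacing")
    alpha_step: float = Field(0.05, gt=0, description="allocation choice spacing")

    # --- initial condition of forward simulations --------------------------
    L_init: float = Field(5.0, gt=0, description="length at age 1, cm")

    @model_validator(mode="after")
    def _check_grids(self) -> "ModelParams":
        if self.L_max <= self.L_min:
            raise ValueError("L_max must exceed L_min")
        if self.L_init < self.L_min or self.L_init > self.L_max:
            raise ValueError("L_init must lie inside the length grid")
        return self

    # Grids are derived, not stored, so the hash covers them via the scalars.
    def length_grid(self) -> np.ndarray:
        n = int(round((self.L_max - self.L_min) / self.L_step)) + 1
        return self.L_min + self.L_step * np.arange(n)

    def phi_grid(self) -> np.ndarray:
        n = int(round(self.phi_max / self.phi_step)) + 1
        grid = self.phi_step * np.arange(n)
        # the reference strategy must be an available choice
        if not np.any(np.isclose(grid, self.phi_ref)):
            grid = np.sort(np.append(grid, self.phi_ref))
        return grid

    def alpha_grid(self) -> np.ndarray:
        n = int(round(1.0 / self.alpha_step)) + 1
        grid = self.alpha_step * np.arange(n)
        grid[-1] = 1.0
        return grid


class FishingScenario(_Frozen):
    """One harvest regime: baseline rate ``F0`` and behavioral selectivity.

    ``gamma`` spans a continuum of gear types: negative values target
    hiding/resting fish (purse-seine-like), zero is behavior-unselective,
    positive values target actively foraging fish (baited-gear-like).
    Realized fishing mortality is
    ``F = (1 − γ)·F0 + γ·(φ/φ̄)·F0``, floored at zero.
    """

    F0: float = Field(0.0, ge=0, description="baseline fishing mortality, 1/yr")
    gamma: float = Field(0.0, ge=-1.0, le=1.0, description="behavioral gear selectivity")

    @classmethod
    def unfished(cls) -> "FishingScenario":
        return cls(F0=0.0, gamma=0.0)
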