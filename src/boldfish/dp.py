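"""Backward-induction solver for the optimal foraging / allocation policy.

The decision problem: at every state (age, length node, food-availability
node) choose the foraging intensity ``phi`` and the gonad-allocation
fraction ``alpha`` for the coming year so as to maximize expected lifetime
gonad production,

    V(age, L, E) = max_{phi, alpha}  S·( G_spawn + Σ_{E'} P(E'|E)·V(age+1, L', E') ),

where ``S`` is the probability of surviving the year, ``G_spawn`` the gonads
released at the year-end spawning, and ``L'`` the year-end length
(interpolated linearly between length nodes).  ``V(T_max+1, ·, ·) = 0``.

The within-year integration is independent of both age and the fishing
scenario — fishing only multiplies survival by the constant ``exp(−F(phi))``
— so the expensive state×choice tensor (:class:`YearTable`) is built once
per parameter set and reused across every ``(F0, gamma)`` scenario and age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import model_core
from .forage import ForageChain, ForageProcess
from .params import FishingScenario, ModelParams

__all__ = [
    "StateGrid",
    "YearTable",
    "Policy",
    "build_state_grid",
    "build_year_table",
    "solve_policy",
    "expected_continuation",
]


@dataclass(frozen=True)
class StateGrid:
    """Discretization of states (age × length × food) and choices (φ × α)."""

    ages: np.ndarray           # 1..T_max
    lengths: np.ndarray        # cm, strictly increasing
    chain: ForageChain         # discretized forage process
    phis: np.ndarray           # includes 0 and the reference φ̄
    alphas: np.ndarray         # includes 0 and 1

    def __post_init__(self) -> None:
        for g in (self.lengths, self.phis, self.alphas):
            if np.any(np.diff(g) <= 0):
                raise ValueError("grids must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.ages), len(self.lengths), self.chain.n_nodes)


def build_state_grid(params: ModelParams) -> StateGrid:
    process = ForageProcess.from_params(params)
    chain = process.discretize(params.n_E_nodes, span_sd=params.E_span_sd)
    return StateGrid(
        ages=np.arange(1, params.T_max + 1),
        lengths=params.length_grid(),
        chain=chain,
        phis=params.phi_grid(),
        alphas=params.alpha_grid(),
    )


@dataclass
class YearTable:
    """One-year outcomes for every (length, E, φ, α) combination.

    Scenario- and age-independent: stores spawned gonads, natural survival,
    year-end length (as interpolation indices/weights into the length grid)
    and starvation flags.  ``n_grid_escapes`` counts year-end lengths beyond
    the top length node (clamped there).
    """

    grid: StateGrid
    G_spawn: np.ndarray            # (nL, nE, nP, nA)
    natural_survival: np.ndarray
    natural_mortality: np.ndarray  # time-averaged annual natural rate
    L_end: np.ndarray
    idx_lo: np.ndarray             # lower length-node index of L_end
    w_hi: np.ndarray               # weight on the upper node
    starved: np.ndarray
    n_grid_escapes: int = 0


def build_year_table(params: ModelParams, grid: StateGrid | None = None) -> YearTable:
    grid = grid or build_state_grid(params)
    L = grid.lengths[:, None, None, None]
    E = grid.chain.nodes[None, :, None, None]
    phi = grid.phis[None, None, :, None]
    alpha = grid.alphas[None, None, None, :]
    W = model_core.weight_from_length(grid.lengths, params)[:, None, None, None]

    out = model_core.step_within_year(W, 0.0, L, phi, alpha, E,
                                      FishingScenario.unfished(), params)

    lengths = grid.lengths
    step = lengths[1] - lengths[0] if len(lengths) > 1 else 1.0
    escapes = int(np.count_nonzero(out.L_end > lengths[-1] + 1e-9))
    if escapes:
        warnings.warn(
            f"{escapes} year-end lengths exceeded the top length node "
            f"({lengths[-1]} cm) and were clamped; consider raising L_max.",
            RuntimeWarning, stacklevel=2)
    if len(lengths) > 1:
        pos = (out.L_end - lengths[0]) / step
        idx_lo = np.clip(np.floor(pos).astype(np.int32), 0, len(lengths) - 2)
        w_hi = np.clip(pos - idx_lo, 0.0, 1.0)
    else:
        idx_lo = np.zeros(out.L_end.shape, dtype=np.int32)
        w_hi = np.zeros_like(out.L_end)

    return YearTable(grid=grid, G_spawn=out.G_spawn,
                     natural_survival=out.natural_survival,
                     natural_mortality=out.natural_mortality,
                     L_end=out.L_end, idx_lo=idx_lo, w_hi=w_hi,
                     starved=out.starved, n_grid_escapes=escapes)


def expected_continuation(V_next: np.ndarray, L_end, E_index: int,
                          chain: ForageChain, lengths: np.ndarray) -> np.ndarray:
    """E over next year's food of the next-age value at year-end length.

    ``Σ_{E'} P(E'|E)·interp_L(V_next(·, E'), L_end)`` with linear length
    interpolation, clamped at the grid ends.  ``V_next`` has shape
    (n_lengths, n_E_nodes).
    """
    if not np.all(np.isfinite(V_next)):
        raise ValueError("next-age value grid contains non-finite entries")
    vbar = V_next @ chain.transition[E_index]          # (nL,)
    L_end = np.asarray(L_end, dtype=float)
    return np.interp(L_end, lengths, vbar)


@dataclass
class Policy:
    """Optimal (φ*, α*) and the value grid over (age, length node, E node).

    Arrays are indexed ``[age, iL, iE]`` with a dead row at age 0 so that
    ages index directly.  ``params_hash`` ties the policy to the exact
    parameter set it was solved under.
    """

    grid: StateGrid
    phi: np.ndarray
    alpha: np.ndarray
    V: np.ndarray
    scenario: FishingScenario
    params_hash: str
    clamp_count: int = 0
    n_grid_escapes: int = 0
    meta: dict = field(default_factory=dict)

    def lookup(self, age: int, L, E) -> tuple[np.ndarray, np.ndarray]:
        """(φ*, α*) at an age for lengths (nearest node) and E (nearest node)."""
        lengths = self.grid.lengths
        if len(lengths) == 1:
            iL = np.zeros(np.shape(L), dtype=int)
        else:
            iL = np.clip(np.round(
                (np.asarray(L, dtype=float) - lengths[0])
                / (lengths[1] - lengths[0])).astype(int), 0, len(lengths) - 1)
        iE = self.grid.chain.nearest_node(E)
        return self.phi[age, iL, iE], self.alpha[age, iL, iE]

    def value_at(self, age: int, L: float, E_index: int) -> float:
        """Value at an exact length node (nearest) and E node."""
        iL = int(np.abs(self.grid.lengths - L).argmin())
        return float(self.V[age, iL, E_index])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: age, L, E, phi, alpha, V."""
        ages = self.grid.ages
        nA, nL, nE = len(ages), len(self.grid.lengths), self.grid.chain.n_nodes
        ia, il, ie = np.meshgrid(ages, np.arange(nL), np.arange(nE), indexing="ij")
        return pd.DataFrame({
            "age": ia.ravel(),
            "L": self.grid.lengths[il.ravel()],
            "E": self.grid.chain.nodes[ie.ravel()],
            "phi": self.phi[1:].ravel(),
            "alpha": self.alpha[1:].ravel(),
            "V": self.V[1:].ravel(),
        })


def solve_policy(params: ModelParams, scenario: FishingScenario,
                 table: YearTable | None = None) -> Policy:
    """Solve the finite-horizon problem by backward induction.

    Ties in the choice maximization break toward lower ``phi`` then lower
    ``alpha`` (the safer strategy), via first-occurrence argmax over the
    C-ordered (φ, α) choice axes.
    """
    table = table if table is not None else build_year_table(params)
    grid = table.grid
    nL, nE = len(grid.lengths), grid.chain.n_nodes
    nP, nA = len(grid.phis), len(grid.alphas)
    T = int(grid.ages[-1])

    clamp = [0]
    F_phi = model_core.fishing_mortality(grid.phis, scenario, params, clamp)
    surv = table.natural_survival * np.exp(-F_phi)[None, None, :, None]
    immediate = surv * table.G_spawn                       # (nL,nE,nP,nA)

    V = np.zeros((T + 2, nL, nE))
    phi_star = np.zeros((T + 1, nL, nE))
    alpha_star = np.zeros((T + 1, nL, nE))
    e_idx = np.arange(nE)[None, :, None, None]

    for age in range(T, 0, -1):
        vbar = V[age + 1] @ grid.chain.transition.T        # (nL, nE): E[V'|E]
        cont = ((1.0 - table.w_hi) * vbar[table.idx_lo, e_idx]
                + table.w_hi * vbar[table.idx_lo + 1, e_idx])
        total = immediate + surv * cont
        flat = total.reshape(nL, nE, nP * nA)
        best = flat.argmax(axis=2)
        V[age] = np.take_along_axis(flat, best[:, :, None], axis=2)[:, :, 0]
        phi_star[age] = grid.phis[best // nA]
        alpha_star[age] = grid.alphas[best % nA]
        if not np.all(np.isfinite(V[age])):
            raise FloatingPointError("non-finite value encountered in backward induction")

    return Policy(grid=grid, phi=phi_star, alpha=alpha_star, V=V[: T + 1],
                  scenario=scenario, params_hash=params.content_hash(),
                  clamp_count=clamp[0], n_grid_escapes=table.n_grid_escapes)
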