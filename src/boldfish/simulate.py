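"""Monte-Carlo forward simulation of individuals following the optimal policy.

Each replicate draws an independent annual food-availability path, looks up
the optimal (φ*, α*) at its current (age, length, nearest-E-node) state, and
integrates one year with the same bioenergetic core used by the solver.
Survival is propagated as a probability (expected-survivorship accounting):
state dynamics do not depend on whether an individual is removed by
mortality, so trait statistics are computed over all replicates while
survival enters only the fitness bookkeeping.  The exception is starvation,
which does alter state; starved replicates are frozen and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import model_core
from .dp import Policy
from .forage import ForageProcess
from .params import FishingScenario, ModelParams

__all__ = ["Trajectory", "TraitSummary", "simulate_individual", "simulate_population"]

#: per-age traits recorded for every replicate
TRAITS = ("length", "phi", "alpha", "natural_mortality", "F", "gsi", "G_spawn")


@dataclass(frozen=True)
class Trajectory:
    """One individual's life: per-age records plus maturation/starvation flags.

    ``records`` columns: age, length (start of year, cm), phi, alpha,
    natural_mortality and F (time-averaged annual rates), gsi (at the
    year-end spawning), G_spawn (g), survival (cumulative to year end).
    """

    records: pd.DataFrame
    age_at_maturity: int | None
    starved: bool
    fitness: float  # realized Σ_age survival-to-year-end × G_spawn


@dataclass
class TraitSummary:
    """Population summary over replicates: per-age trait means/SDs.

    ``by_age`` is tidy: columns (age, trait, mean, sd).  ``maturity_counts``
    is the distribution of age at first maturation (first age with α* > 0 on
    the realized path).  ``mean_fitness``/``se_fitness`` use the
    expected-survivorship fitness of each replicate.
    """

    by_age: pd.DataFrame
    maturity_counts: pd.Series
    n_replicates: int
    seed: object
    mean_fitness: float
    se_fitness: float
    starved_fraction: float
    mean_E_node_distance: float  # mean |E − nearest node| / node spacing
    meta: dict = field(default_factory=dict)

    def trait_at(self, age: int, trait: str, stat: str = "mean") -> float:
        sel = self.by_age[(self.by_age.age == age) & (self.by_age.trait == trait)]
        return float(sel[stat].iloc[0])

    def mean_age_at_maturity(self) -> float:
        counts = self.maturity_counts
        return float((counts.index.to_numpy() * counts.to_numpy()).sum() / counts.sum())


def _check_policy(policy: Policy, params: ModelParams, scenario: FishingScenario) -> None:
    if policy.params_hash != params.content_hash():
        raise ValueError("policy was solved under different model parameters")
    if policy.scenario != scenario:
        raise ValueError("policy was solved under a different fishing scenario")


def _run_cohort(policy: Policy, paths: np.ndarray, params: ModelParams,
                scenario: FishingScenario) -> dict[str, np.ndarray]:
    """Advance a cohort of replicates through life; returns per-age arrays."""
    n, T = paths.shape
    if T < params.T_max:
        raise ValueError("forage paths must cover T_max years")
    L = np.full(n, params.L_init)
    W = np.full(n, float(model_core.weight_from_length(params.L_init, params)))
    surv = np.ones(n)
    frozen = np.zeros(n, dtype=bool)
    out = {t: np.zeros((params.T_max + 1, n)) for t in TRAITS}
    out["survival"] = np.zeros((params.T_max + 1, n))
    fitness = np.zeros(n)
    node_dist = []

    spacing = (np.diff(policy.grid.chain.nodes).mean()
               if policy.grid.chain.n_nodes > 1 else 1.0)
    for age in range(1, params.T_max + 1):
        E = paths[:, age - 1]
        phi, alpha = policy.lookup(age, L, E)
        node_dist.append(np.abs(E - policy.grid.chain.nodes[
            policy.grid.chain.nearest_node(E)]) / spacing)
        step = model_core.step_within_year(W, 0.0, L, phi, alpha, E,
                                           scenario, params)
        out["length"][age] = L
        out["phi"][age] = phi
        out["alpha"][age] = alpha
        out["natural_mortality"][age] = step.natural_mortality
        out["F"][age] = step.F
        out["gsi"][age] = step.Q_spawn
        surv_new = np.where(frozen, surv, surv * step.survival)
        g_spawn = np.where(frozen, 0.0, step.G_spawn)
        out["G_spawn"][age] = g_spawn
        out["survival"][age] = surv_new
        fitness += surv_new * g_spawn
        W = np.where(frozen, W, step.W_end)
        L = np.where(frozen, L, step.L_end)
        surv = surv_new
        frozen |= step.starved

    first_mature = np.where(out["alpha"][1:] > 0, 1, 0).argmax(axis=0)
    matured = out["alpha"][1:].max(axis=0) > 0
    out["age_at_maturity"] = np.where(matured, first_mature + 1, -1)
    out["fitness"] = fitness
    out["frozen"] = frozen
    out["node_dist"] = float(np.mean(node_dist))
    return out


def simulate_individual(policy: Policy, forage_path: np.ndarray,
                        params: ModelParams, scenario: FishingScenario) -> Trajectory:
    """Deterministic life given a fixed annual food-availability path."""
    _check_policy(policy, params, scenario)
    res = _run_cohort(policy, np.asarray(forage_path, dtype=float)[None, :],
                      params, scenario)
    ages = np.arange(1, params.T_max + 1)
    records = pd.DataFrame({"age": ages})
    for t in TRAITS + ("survival",):
        records[t] = res[t][1:, 0]
    mat = int(res["age_at_maturity"][0])
    return Trajectory(records=records,
                      age_at_maturity=mat if mat > 0 else None,
                      starved=bool(res["frozen"][0]),
                      fitness=float(res["fitness"][0]))


def simulate_population(policy: Policy, n_replicates: int, seed,
                        params: ModelParams, scenario: FishingScenario,
                        process: ForageProcess | None = None,
                        paths: np.ndarray | None = None) -> TraitSummary:
    """Simulate ``n_replicates`` independent lives and summarize trait fields.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``; identical
    seeds give bit-identical summaries.  ``paths`` may supply pre-drawn
    forage paths of shape ``(n_replicates, T_max)`` (e.g. node-valued chain
    paths for consistency checks), bypassing the AR(1) sampler.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    _check_policy(policy, params, scenario)
    if paths is None:
        process = process or ForageProcess.from_params(params)
        rng = np.random.default_rng(seed)
        paths = process.sample_paths(n_replicates, params.T_max, rng)
    else:
        paths = np.asarray(paths, dtype=float)
        if paths.shape[0] != n_replicates:
            raise ValueError("paths must have one row per replicate")
    res = _run_cohort(policy, paths, params, scenario)

    rows = []
    for trait in TRAITS:
        arr = res[trait][1:]                     # (T_max, n)
        rows.append(pd.DataFrame({
            "age": np.arange(1, params.T_max + 1),
            "trait": trait,
            "mean": arr.mean(axis=1),
            "sd": arr.std(axis=1),
        }))
    by_age = pd.concat(rows, ignore_index=True)

    mat = res["age_at_maturity"]
    maturity_counts = pd.Series(mat[mat > 0]).value_counts().sort_index()
    fit = res["fitness"]
    return TraitSummary(
        by_age=by_age,
        maturity_counts=maturity_counts,
        n_replicates=n_replicates,
        seed=seed,
        mean_fitness=float(fit.mean()),
        se_fitness=float(fit.std(ddof=1) / np.sqrt(n_replicates)) if n_replicates > 1 else 0.0,
        starved_fraction=float(res["frozen"].mean()),
        mean_E_node_distance=res["node_dist"],
    )
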