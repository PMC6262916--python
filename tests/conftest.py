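"""Shared fixtures: parameter sets, cached year tables, and a brute-force
dynamic-programming oracle implemented independently of the vectorized solver."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from boldfish import model_core
from boldfish.dp import build_state_grid, build_year_table
from boldfish.params import FishingScenario, ModelParams

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def default_table(params):
    """The (expensive) within-year tensor for the default parameters."""
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return build_year_table(params)


@pytest.fixture()
def tiny_params() -> ModelParams:
    """A 2-age, 3-length, 1-food-node instance with 2×3 choices per state:
    36 strategy sequences, small enough for exhaustive enumeration."""
    return ModelParams(T_max=2, n_E_nodes=1,
                       L_min=5.0, L_max=25.0, L_step=10.0, L_init=5.0,
                       phi_max=1.4, phi_step=1.4, alpha_step=0.5,
                       n_substeps=4)


def brute_force_solve(params: ModelParams, scenario: FishingScenario):
    """Exhaustive scalar-recursion solver for tiny instances.

    Evaluates every (φ, α) choice at every state with plain Python loops and
    scalar within-year integration; continuation uses the same linear length
    interpolation contract as the solver (np.interp over the length nodes)
    and an explicit sum over next-year food nodes.  Returns V, φ*, α*
    indexed [age, iL, iE].
    """
    grid = build_state_grid(params)
    lengths, chain = grid.lengths, grid.chain
    nL, nE, T = len(lengths), chain.n_nodes, params.T_max
    V = np.zeros((T + 2, nL, nE))
    phi_star = np.zeros((T + 1, nL, nE))
    alpha_star = np.zeros((T + 1, nL, nE))
    for age in range(T, 0, -1):
        for iL, L in enumerate(lengths):
            W = float(model_core.weight_from_length(L, params))
            for iE in range(nE):
                best, best_choice = -np.inf, (0.0, 0.0)
                for phi in grid.phis:
                    for alpha in grid.alphas:
                        out = model_core.step_within_year(
                            W, 0.0, L, float(phi), float(alpha),
                            float(chain.nodes[iE]), scenario, params)
                        cont = 0.0
                        for jE in range(nE):
                            cont += chain.transition[iE, jE] * float(
                                np.interp(out.L_end, lengths, V[age + 1, :, jE]))
                        val = float(out.survival) * (float(out.G_spawn) + cont)
                        if val > best + 1e-15:
                            best, best_choice = val, (float(phi), float(alpha))
                V[age, iL, iE] = max(best, 0.0) if best > -np.inf else 0.0
                phi_star[age, iL, iE], alpha_star[age, iL, iE] = best_choice
    return V[: T + 1], phi_star, alpha_star
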