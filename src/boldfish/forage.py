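"""Stochastic annual food availability: a stationary Gaussian AR(1) process.

The forage environment ``E`` has stationary mean ``mu_E``, stationary SD
``sigma_E`` and lag-1 autocorrelation ``rho_E``:

    E[t+1] = mu_E + rho·(E[t] − mu_E) + ε,   ε ~ N(0, sigma_E²·(1 − rho²)).

Two views of the same process are provided:

* :meth:`ForageProcess.sample_path` / :meth:`sample_paths` — simulated annual
  values for the forward simulation (optionally floored at zero, since
  negative food availability is meaningless; the model core additionally
  treats E as max(E, 0) in the intake term).
* :meth:`ForageProcess.discretize` — a Tauchen-style finite Markov chain used
  by the dynamic-programming solver to take expectations over next year's
  food availability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .params import ModelParams

__all__ = ["ForageProcess", "ForageChain"]


@dataclass(frozen=True)
class ForageChain:
    """Discretized forage process: node values and one-year transitions.

    ``transition[i, j] = P(E' = nodes[j] | E = nodes[i])``; rows sum to one.
    ``marginal`` is the stationary distribution of the chain.
    """

    nodes: np.ndarray
    transition: np.ndarray
    marginal: np.ndarray

    def __post_init__(self) -> None:
        rowsum = self.transition.sum(axis=1)
        if not np.allclose(rowsum, 1.0, atol=1e-12):
            raise ValueError("transition rows must sum to 1")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def stationary_mean(self) -> float:
        return float(self.marginal @ self.nodes)

    def stationary_sd(self) -> float:
        m = self.stationary_mean()
        return float(np.sqrt(self.marginal @ (self.nodes - m) ** 2))

    def nearest_node(self, E) -> np.ndarray:
        """Index of the closest node for each entry of ``E``."""
        return np.abs(np.asarray(E, dtype=float)[..., None] - self.nodes).argmin(axis=-1)

    def simulate(self, T: int, rng: np.random.Generator) -> np.ndarray:
        """Sample a node-index path of length T from the chain itself."""
        idx = np.empty(T, dtype=int)
        idx[0] = rng.choice(self.n_nodes, p=self.marginal)
        cum = np.cumsum(self.transition, axis=1)
        u = rng.random(T)
        for t in range(1, T):
            idx[t] = np.searchsorted(cum[idx[t - 1]], u[t])
        return idx

    def to_frame(self) -> pd.DataFrame:
        """Transition table in long form, for export/inspection."""
        i, j = np.meshgrid(range(self.n_nodes), range(self.n_nodes), indexing="ij")
        return pd.DataFrame({
            "E_from": self.nodes[i.ravel()],
            "E_to": self.nodes[j.ravel()],
            "prob": self.transition.ravel(),
        })


@dataclass(frozen=True)
class ForageProcess:
    mu: float
    sigma: float
    rho: float
    truncate_at_zero: bool = True

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not -1.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [-1, 1)")

    @classmethod
    def from_params(cls, params: ModelParams, truncate_at_zero: bool = True) -> "ForageProcess":
        return cls(mu=params.mu_E, sigma=params.sigma_E, rho=params.rho_E,
                   truncate_at_zero=truncate_at_zero)

    @property
    def innovation_sd(self) -> float:
        return self.sigma * np.sqrt(1.0 - self.rho**2)

    def sample_paths(self, n_paths: int, T: int,
                     rng: np.random.Generator | int | None = None) -> np.ndarray:
        """``(n_paths, T)`` array of annual E values, stationary start."""
        if T < 1:
            raise ValueError("need at least one year")
        rng = np.random.default_rng(rng)
        out = np.empty((n_paths, T))
        dev = rng.normal(0.0, self.sigma, size=n_paths)
        out[:, 0] = self.mu + dev
        eps = rng.normal(0.0, self.innovation_sd, size=(n_paths, max(T - 1, 0)))
        for t in range(1, T):
            dev = self.rho * dev + eps[:, t - 1]
            out[:, t] = self.mu + dev
        if self.truncate_at_zero:
            np.maximum(out, 0.0, out=out)
        return out

    def sample_path(self, T: int, rng: np.random.Generator | int | None = None) -> np.ndarray:
        return self.sample_paths(1, T, rng)[0]

    def truncation_fraction(self, paths: np.ndarray) -> float:
        """Fraction of values sitting on the zero floor (log-worthy diagnostic)."""
        return float(np.mean(paths <= 0.0))

    def discretize(self, n_nodes: int, span_sd: float = 3.0) -> ForageChain:
        """Tauchen discretization: evenly spaced nodes over ±``span_sd``·σ.

        Transition probabilities integrate the conditional normal over the
        midpoint bins.  Node values are kept symmetric about the mean (they
        may dip below zero for wide spans; the model core floors E at zero
        where it enters food intake).  With ``rho = 0`` every row equals the
        marginal; ``n_nodes = 1`` degenerates to a point mass at the mean.
        """
        if n_nodes < 1:
            raise ValueError("need at least one node")
        if n_nodes == 1:
            return ForageChain(nodes=np.array([self.mu]),
                               transition=np.ones((1, 1)),
                               marginal=np.ones(1))
        nodes = self.mu + np.linspace(-span_sd, span_sd, n_nodes) * self.sigma
        edges = 0.5 * (nodes[1:] + nodes[:-1])
        cond_mean = self.mu + self.rho * (nodes - self.mu)  # (n,)
        cdf = stats.norm.cdf(edges[None, :], loc=cond_mean[:, None],
                             scale=self.innovation_sd)
        trans = np.diff(np.concatenate(
            [np.zeros((n_nodes, 1)), cdf, np.ones((n_nodes, 1))], axis=1), axis=1)
        marginal = _stationary_distribution(trans)
        return ForageChain(nodes=nodes, transition=trans, marginal=marginal)


def _stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Left eigenvector of the transition matrix for eigenvalue 1."""
    vals, vecs = np.linalg.eig(transition.T)
    i = np.argmin(np.abs(vals - 1.0))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()
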