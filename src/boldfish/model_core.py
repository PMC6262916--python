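"""Bioenergetics, mortality components, and the within-year state update.

All functions broadcast over numpy arrays, so the same code path serves
scalar sanity checks, the dynamic-programming state×choice tensor, and the
replicate-vectorized forward simulation.

State variables
---------------
``L``   body length (cm), irreversible: reported length is a running maximum.
``W``   somatic mass (g), tied to length through ``W = k·L³``.
``G``   gonad mass (g), built during the year, spawned (and reset) at year end.
``E``   annual food availability (dimensionless scale of the forage process).

Rates are annual (1/yr).  Within a year the continuous dynamics are advanced
with ``n_substeps`` forward-Euler substeps while the behavioral choices
(foraging intensity ``phi`` and allocation-to-gonads fraction ``alpha``)
are held constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import FishingScenario, ModelParams

__all__ = [
    "BodyState",
    "MortalityBreakdown",
    "YearOutcome",
    "weight_from_length",
    "length_from_weight",
    "food_intake",
    "net_intake",
    "gsi",
    "fishing_mortality",
    "size_mortality",
    "reproduction_mortality",
    "foraging_mortality",
    "total_mortality",
    "step_within_year",
]

# Somatic mass floor (g) used purely to keep powers finite after a
# starvation death has already been flagged; flagged entries carry no value.
_W_FLOOR = 1e-9


@dataclass(frozen=True)
class BodyState:
    """Individual state at the start of a year."""

    age: int
    L: float
    W: float
    G: float = 0.0
    E_current: float = 0.0

    def __post_init__(self) -> None:
        if self.L <= 0 or self.W <= 0 or self.G < 0:
            raise ValueError("BodyState requires L > 0, W > 0, G >= 0")

    @classmethod
    def from_length(cls, age: int, L: float, params: ModelParams,
                    G: float = 0.0, E_current: float = 0.0) -> "BodyState":
        return cls(age=age, L=L, W=float(weight_from_length(L, params)),
                   G=G, E_current=E_current)


@dataclass(frozen=True)
class MortalityBreakdown:
    """The five instantaneous mortality components and their exact sum (1/yr)."""

    M_fixed: float
    M_size: float
    M_reproduction: float
    M_foraging: float
    F: float
    Z_total: float = field(default=np.nan)

    def __post_init__(self) -> None:
        total = self.M_fixed + self.M_size + self.M_reproduction + self.M_foraging + self.F
        if np.isnan(self.Z_total):
            object.__setattr__(self, "Z_total", total)
        elif self.Z_total != total:
            raise ValueError("Z_total must equal the sum of the five components")
    natural = property(lambda self: self.Z_total - self.F)


def weight_from_length(L, params: ModelParams):
    """Somatic mass from length, ``W = k·L³`` (g)."""
    L = np.asarray(L, dtype=float)
    if np.any(L <= 0):
        raise ValueError("length must be positive")
    return params.k * L**3


def length_from_weight(W, params: ModelParams):
    """Inverse length-weight map, ``L = (W/k)^(1/3)`` (cm)."""
    W = np.asarray(W, dtype=float)
    if np.any(W <= 0):
        raise ValueError("somatic mass must be positive")
    return (W / params.k) ** (1.0 / 3.0)


def food_intake(phi, E):
    """Food intake ``h = φ·E``; negative food availability yields nothing."""
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0):
        raise ValueError("foraging intensity must be non-negative")
    return phi * np.maximum(np.asarray(E, dtype=float), 0.0)


def net_intake(h, W, G, params: ModelParams):
    """Net energy gain ``R = h·W^b − b0·(W+G)^a`` (g/yr); negative = starvation."""
    W = np.asarray(W, dtype=float)
    if np.any(W <= 0):
        raise ValueError("somatic mass must be positive")
    G = np.asarray(G, dtype=float)
    return h * W**params.b - params.b0 * (W + G) ** params.a


def gsi(W, G):
    """Gonado-somatic index ``Q = G/(W+G)``."""
    W = np.asarray(W, dtype=float)
    G = np.asarray(G, dtype=float)
    return G / (W + G)


def fishing_mortality(phi, scenario: FishingScenario, params: ModelParams,
                      clamp_counter: list | None = None):
    """Behavior-dependent fishing mortality (1/yr).

    ``F = (1−γ)·F0 + γ·(φ/φ̄)·F0``: an unavoidable component plus a component
    proportional to foraging activity.  At ``φ = φ̄`` the two collapse and
    ``F = F0`` for every γ.  The linear form can go negative for extreme
    ``φ/φ̄`` under strong selectivity; such values are floored at zero and,
    when ``clamp_counter`` (a single-element list) is supplied, counted.
    """
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0):
        raise ValueError("foraging intensity must be non-negative")
    g, F0 = scenario.gamma, scenario.F0
    raw = (1.0 - g) * F0 + g * (phi / params.phi_ref) * F0
    clamped = np.maximum(raw, 0.0)
    if clamp_counter is not None:
        clamp_counter[0] += int(np.count_nonzero(raw < 0.0))
    return clamped


def size_mortality(L, params: ModelParams):
    """Size-dependent predation ``M_size = c·L^d`` (1/yr), declining with length."""
    L = np.asarray(L, dtype=float)
    if np.any(L <= 0):
        raise ValueError("length must be positive")
    return params.c * L**params.d


def reproduction_mortality(Q, L, params: ModelParams):
    """Cost of carrying gonads: ``M_size·(Q/q_ref)^p``; equals M_size at Q=q_ref."""
    Q = np.asarray(Q, dtype=float)
    if np.any(Q < 0) or np.any(Q >= 1):
        raise ValueError("GSI must lie in [0, 1)")
    return size_mortality(L, params) * (Q / params.q_ref) ** params.p


def foraging_mortality(phi, L, params: ModelParams):
    """Activity exposure: ``(φ/φ̄)^x·M_size``; equals M_size at the reference φ̄."""
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0):
        raise ValueError("foraging intensity must be non-negative")
    return (phi / params.phi_ref) ** params.phi_foraging_mort_exp * size_mortality(L, params)


def total_mortality(state: BodyState, phi: float, scenario: FishingScenario,
                    params: ModelParams) -> MortalityBreakdown:
    """All five instantaneous mortality components at a given state and behavior."""
    Q = float(gsi(state.W, state.G))
    m_size = float(size_mortality(state.L, params))
    m_rep = float(reproduction_mortality(Q, state.L, params))
    m_for = float(foraging_mortality(phi, state.L, params))
    f = float(fishing_mortality(phi, scenario, params))
    return MortalityBreakdown(M_fixed=params.M_fixed, M_size=m_size,
                              M_reproduction=m_rep, M_foraging=m_for, F=f)


@dataclass(frozen=True)
class YearOutcome:
    """Result of integrating one year of life (arrays broadcast like the inputs).

    ``M_*`` fields are the within-year time averages of the instantaneous
    components, so e.g. ``exp(-(M_fixed+M_size+M_reproduction+M_foraging))``
    is the survival from natural causes alone.  ``G_spawn`` is the gonad mass
    released at the year-end spawning event; the year-end state has ``G = 0``.
    """

    W_end: np.ndarray
    L_end: np.ndarray
    G_spawn: np.ndarray
    survival: np.ndarray          # natural × fishing survival over the year
    natural_survival: np.ndarray  # exp(−∫ Z_natural dt)
    M_fixed: np.ndarray
    M_size: np.ndarray
    M_reproduction: np.ndarray
    M_foraging: np.ndarray
    F: np.ndarray
    starved: np.ndarray           # somatic mass driven to zero during the year

    @property
    def natural_mortality(self) -> np.ndarray:
        return self.M_fixed + self.M_size + self.M_reproduction + self.M_foraging

    @property
    def Q_spawn(self) -> np.ndarray:
        return gsi(self.W_end, self.G_spawn)


def step_within_year(W, G, L, phi, alpha, E, scenario: FishingScenario,
                     params: ModelParams,
                     clamp_counter: list | None = None) -> YearOutcome:
    """Advance one year of growth, reproduction, and survival.

    Forward-Euler with ``Δt = 1/n_substeps``.  Each substep evaluates the
    natural mortality components and the net intake ``R`` at the current
    state; surplus energy (``R ≥ 0``) is split ``alpha`` to gonads and
    ``1 − alpha`` to soma, while a deficit is paid by soma alone (gonads are
    not resorbed).  Length follows the running maximum of the length-weight
    inverse, i.e. fish never shrink in length.  Fishing mortality is constant
    within the year (it depends only on ``phi``), so year survival factorizes
    into natural survival times ``exp(−F)``.

    Individuals whose somatic mass reaches zero are flagged ``starved``:
    their survival and spawned gonads are zeroed.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha < 0) or np.any(alpha > 1):
        raise ValueError("allocation must lie in [0, 1]")
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0):
        raise ValueError("foraging intensity must be non-negative")

    dt = 1.0 / params.n_substeps
    h = food_intake(phi, E)
    phi_exposure = (phi / params.phi_ref) ** params.phi_foraging_mort_exp

    shape = np.broadcast_shapes(np.shape(W), np.shape(G), np.shape(L),
                                np.shape(phi), np.shape(alpha), np.shape(E))
    W = np.broadcast_to(np.asarray(W, dtype=float), shape).copy()
    G = np.broadcast_to(np.asarray(G, dtype=float), shape).copy()
    L = np.broadcast_to(np.asarray(L, dtype=float), shape).copy()
    if np.any(W <= 0) or np.any(L <= 0):
        raise ValueError("initial W and L must be positive")
    L = np.maximum(L, length_from_weight(np.maximum(W, _W_FLOOR), params))

    m_size_int = np.zeros(shape)
    m_rep_int = np.zeros(shape)
    m_for_int = np.zeros(shape)
    starved = np.zeros(shape, dtype=bool)

    for _ in range(params.n_substeps):
        m_size = params.c * L**params.d
        Q = G / (W + G)
        m_rep = m_size * (Q / params.q_ref) ** params.p
        m_for = phi_exposure * m_size
        m_size_int += m_size * dt
        m_rep_int += m_rep * dt
        m_for_int += m_for * dt

        R = h * W**params.b - params.b0 * (W + G) ** params.a
        surplus = R >= 0
        G = G + np.where(surplus, alpha * R, 0.0) * dt
        W = W + np.where(surplus, (1.0 - alpha) * R, R) * dt
        starved |= W <= 0
        W = np.maximum(W, _W_FLOOR)
        L = np.maximum(L, length_from_weight(W, params))

    natural_rate = params.M_fixed + m_size_int + m_rep_int + m_for_int
    natural_survival = np.where(starved, 0.0, np.exp(-natural_rate))
    F = np.broadcast_to(fishing_mortality(phi, scenario, params, clamp_counter),
                        shape)
    survival = natural_survival * np.exp(-F)
    G_spawn = np.where(starved, 0.0, G)

    return YearOutcome(
        W_end=W, L_end=L, G_spawn=G_spawn,
        survival=survival, natural_survival=natural_survival,
        M_fixed=np.broadcast_to(np.asarray(params.M_fixed, dtype=float), shape),
        M_size=m_size_int, M_reproduction=m_rep_int, M_foraging=m_for_int,
        F=F, starved=starved,
    )
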