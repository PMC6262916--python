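# Methods

## Model

`boldfish` finds evolutionary endpoints of foraging behavior and life
history under behavior-selective harvest: the state-dependent strategy
(φ*, α*) that maximizes expected lifetime gonad production, computed by
backward induction, then expressed as population trait distributions by
Monte-Carlo forward simulation. Optimization stands in for evolution —
endpoints are the adaptations expected given enough time under constant
conditions; no genetics or trait transmission is modeled, and there is no
density dependence or population feedback.

### States, choices, fitness

State: age *t* ∈ {1..T_max}, length *L*, and the current annual food
availability *E*. Somatic mass is slaved to length via *W* = k·L³ when a
year begins; within the year *W* and gonads *G* evolve continuously while
*L* is the running maximum of (W/k)^(1/3) — fish do not shrink in length,
though somatic mass may dip. Choices (annual resolution): foraging
intensity φ (risk acceptance; scales both intake and exposure) and the
fraction α of surplus energy allocated to gonads. Fitness is the expected
sum over years of (survival to the year-end spawning) × (gonads spawned),
with terminal value zero after T_max.

### Within-year dynamics

The continuous bioenergetics are integrated with forward Euler in
`n_substeps = 24` steps per year. Per substep: net intake
R = φ·E·W^b − b0·(W+G)^a at the current state; if R ≥ 0 it is split α to
gonads and (1−α) to soma, a deficit is paid entirely by soma (gonads are
retained, not resorbed — a modeling choice; the alternative, resorption,
would soften starvation costs). Mortality components are accumulated at the
current state, so reproduction mortality tracks the growing gonad load
through the year. If somatic mass reaches zero the individual is flagged
starved: survival and spawn are zeroed (solver) or the replicate is frozen
(simulator). At the defaults starvation occurs only in pathological states,
never in simulated populations.

Fishing mortality F = (1−γ)F0 + γ(φ/φ̄)F0 depends only on the year's φ, so
annual survival factorizes as exp(−∫Z_nat dt)·exp(−F). F is floored at
zero; the floor can only bind for φ/φ̄ > (1−γ)/(−γ) with γ < 0 (φ > 6.07 at
γ = −0.3), outside the default choice grid, and every solve counts and
reports clamps.

### Parameters

Bioenergetics and mortality (dimensionless unless noted):

| symbol | default | meaning |
| --- | --- | --- |
| a, b | 0.7, 0.7 | metabolic cost / intake mass exponents |
| b0 | 0.3 | metabolic cost coefficient |
| k | 0.95 g/cm³ | length–weight coefficient, W = k·L³ |
| c, d | 1.2 /yr, −0.75 | size-dependent mortality M_size = c·L^d |
| p | 2 | gonad-load mortality exponent |
| q_ref | 0.2 | GSI at which M_reproduction = M_size |
| φ̄ | 1.4 | reference foraging strategy (fishing-selectivity pivot) |
| M_fixed | 0.05 /yr | background mortality |
| x | 2 | foraging-exposure exponent, M_foraging = (φ/φ̄)^x·M_size |

Forage environment: μ_E = 6, σ_E = 2.5, lag-1 autocorrelation ρ_E = 0.5.
ρ_E is a package default (autocorrelated forage is part of the model
family's lineage but no strength is canonical); ρ_E = 0 is supported for
sensitivity runs. Sampled paths are floored at zero — negative food is
meaningless — and the model core additionally uses max(E, 0) in the intake
term so that the solver's symmetric node set (whose lowest ±3σ node is
−1.5) stays consistent with simulation.

The functional forms tying Table-style coefficients together (cubic
length–weight, length-based M_size, the (Q/q_ref)^p and (φ/φ̄)^x scalings,
soma-pays-starvation bookkeeping) are this package's explicit reconstruction
of a standard cod-like parameterization; each is an isolated function in
`model_core` precisely so alternatives can be swapped in. The length-based
M_size gives adult natural mortality ≈ 0.04–0.2/yr over 10–100 cm, the
realistic range; a 30 cm fish foraging at φ̄ carries natural Z ≈ 0.24/yr.

### Discretization and numerics

* Length grid 1–130 cm, step 1 cm; the unfished asymptotic length
  (~110 cm) sits inside it. Year-end lengths beyond the top node are clamped
  with a counted warning (they arise only for extreme φ×E choice
  combinations, not along optimal paths).
* Food is discretized by the Tauchen construction: 9 evenly spaced nodes
  over ±3σ with conditional-normal bin probabilities. The chain's
  stationary mean and SD reproduce μ_E within 1% and σ_E within 5%, and a
  simulated chain recovers ρ_E within 0.02 (tested).
* Choice grids: φ ∈ {0, 0.05, …, 4} (81 values, includes φ̄),
  α ∈ {0, 0.05, …, 1}.
* Continuation values are interpolated linearly in length; expectation over
  next year's food uses the Markov transition row. Ties in the choice
  argmax break toward lower φ, then lower α (the safer strategy), making
  solves bit-reproducible.
* The within-year integration tensor over (L, E, φ, α) is independent of
  age and of (F0, γ) — fishing enters survival as the scalar exp(−F(φ)) —
  so one tensor (~4 s) serves every scenario of a sweep; a full solve is
  then < 1 s per scenario.
* Forward simulation propagates survival as a probability rather than
  killing replicates: state dynamics are mortality-independent, so trait
  statistics over all replicates are free of survivor-sampling noise while
  fitness bookkeeping is exact. Policies are looked up at the nearest
  length node and nearest food node; the mean off-node distance is logged.
* T_max = 30 with age 14 as the adult reference age: all scenarios'
  populations are mature well before 14, and 14 is far from the horizon,
  where terminal effects (α → 1, φ → grid max in the last years) live.

### The synthetic environment: what it does and does not emulate

The AR(1) forage process supplies year-to-year variability and persistence
(good and bad food years cluster), which drives the spread of maturation
ages and trait SDs in the population. It does not emulate within-year
(seasonal) forage variation, spatial structure, density-dependent food
competition, or observation error. Passing tests therefore demonstrate
internal consistency of optimization and simulation under the stated
stochastic environment — not predictive accuracy for any real stock.

## Experiment design

The γ sweep holds F0 = 0.1/yr and varies γ from −0.3 to +0.3 in steps of
0.05 (the range argued to be realistic for actual gears), always including
the unselective reference γ = 0 and an unfished baseline. The F sweep
varies F0 from 0 to 0.4/yr at γ ∈ {−0.3, 0, +0.3}. Headline statistics are
extremal percent changes, relative to γ = 0, of the age-14 mean foraging
strategy and emergent natural mortality (Z − F accumulated along realized
lives). Each scenario draws an independent RNG substream from the master
seed, keyed by the canonical scenario (γ coerced to 0 when F0 = 0, where
selectivity is inert), so unfished columns are bit-identical across γ.

Problem sizes: the acceptance script runs the full 13-γ sweep at 10,000
replicates per scenario; the test suite uses 2,000 replicates, at which the
Monte-Carlo standard error of an age-14 trait mean is well under 1% of the
γ-driven contrasts being tested.

## Known limitations

* The reconstructed allocation/growth bookkeeping yields a wider unfished
  maturation spread (ages ~6–24, mean ≈ 14.5) than the tight
  all-mature-by-14 pattern the parameterization is meant to evoke, and
  under gears targeting hiders (γ < 0) the extra intake from elevated
  foraging slightly *increases* age-14 length at low F0 before the usual
  decline sets in. Both trace to the same mechanism: the growth benefit of
  boldness is strong relative to its mortality cost at large size. One
  consequence is that the natural-mortality increase at γ = −0.3 (≈ +8% vs
  unselective fishing) is damped by size-mortality relief and sits below
  the ≈ +20% scale of the behavioral response itself.
* Fishing is purely behavior-selective: no size, age, or maturity
  selectivity (deliberately, to isolate the behavioral route).
* Single-species, no density dependence, no stock–recruitment; yield or
  MSY questions are out of scope.
* Behavior within a year is a single constant φ; no diel or seasonal
  behavioral variation.
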