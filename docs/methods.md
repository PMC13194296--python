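# Methods

## Model and assumptions

The package implements a two-clone Lotka–Volterra competition model of
tumor growth under a cytostatic/cytotoxic dose `u`: sensitive and
resistant cells share one carrying capacity, the drug scales the
sensitive clone's logistic growth by `(1 − d̂_D·u)` (so a full dose with
`d̂_D > 1` actively kills sensitive cells while resources are free), and
the resistant clone is completely insensitive. There is no acquired
resistance: resistant cells at any time descend from the seed present
at `τ = 0`. The dimensionless parameters are obtained by rescaling time
with the sensitive proliferation rate `r_S` and populations with the
carrying capacity `K`; the drug-sensitivity coefficient is doubled in
the rescaling (`d̂_D = 2 d_D`), matching the convention of the
underlying dimensional model.

A general n-species variant (`GeneralModelSpec`, `rhs_general`) extends
this with per-species kill/turnover coefficients and column-sum-zero
transition matrices (spontaneous and drug-induced phenotype switching);
it exists to express the modeling framework and is verified to
specialize exactly to the two-population system. All quantitative
experiments use the two-population model with zero transitions.

States live in the simplex `{s, r ≥ 0, s + r ≤ 1}`, which is invariant
under the dynamics for admissible doses. Instead of the smooth cut-off
used in the existence theory, the integrators carry a guard: a
trajectory with `n > 1.5` or a component below `−10·h` raises
`SimplexGuardError`. The guard is unreachable for admissible controls
(property-tested over random schedules); it exists to catch misuse,
e.g. a custom policy emitting doses far outside `[0, 1]`.

## Parameters

| parameter | meaning | default / range |
|---|---|---|
| `r_S` | sensitive proliferation rate | 0.027 day⁻¹ (prostate cancer under ADT) |
| `d̂_D` | rescaled drug sensitivity | 1.5 (fixed in the reference ensemble) |
| `d̂_T` | relative turnover rate | 0 (most adverse scenario) |
| `r̂_R` | relative resistant proliferation | uniform grid, 25 nodes on [0.5, 1] |
| `f̂_0` | initial resistant fraction | uniform grid, 49 nodes on [0.002, 0.1] |
| `n0` | initial burden / K | 0.25, 0.50, 0.75 |
| `h` | Euler step (normalized) | `r_S/8 = 3.375e-3`, i.e. 8 nodes/day |
| horizon | simulation length | 750 / 1000 / 1500 days matched to `n0` |
| `η` | gradient step size | 0.125 |
| iterations | projected-gradient steps | 500, from `u ≡ 0.5` |

The 49-node `f̂_0` grid takes both endpoints inclusive
(`linspace(0.002, 0.1, 49)`, step ≈ 0.00204); the node count is the
authoritative datum, and an alternative 0.002-step reading shifts
ensemble means by well under a day.

## Numerical scheme and progression statistics

All trajectories use explicit Euler with the fixed step `h`; feedback
policies are re-evaluated at every node (observe the burden, update the
treat/vacation mode with inclusive threshold comparisons, emit the
dose, then step). No adaptive ODE solver is used, so that the adjoint
below differentiates exactly the scheme that produced the trajectories.
Halving the step changes every reported whole-day TTP by at most one
day (tested).

TTP is the first Euler node with `n ≥ 1.2·n0`, censored at the horizon.
TTP′ discretizes the last-exit time `sup{τ : n(τ) ≤ 1.2·n0}`: the last
node at or below the threshold, floored at TTP. The flooring makes the
discrete statistics satisfy `TTP ≤ TTP′` and renders them equal for
protocols that cross the threshold once and monotonically (MTD,
classical adaptive therapy), as the continuous definitions require; for
a grid path the continuous last exit lies between the last below-
threshold node and its successor, and either node is within one step of
the true value. Day reporting: per-tumor values are floored to whole
days; ensemble means are computed on the raw values and rounded
half-up. MTD and On-Off adaptive therapy are scored with TTP, the
surveillance-first Off-On protocol and hyperbolic-cost optimized
schedules with TTP′ (their construction deliberately rides the
threshold early, making first-crossing times uninformative).

## Objective, adjoint, and optimizer

The running cost is integrated with a left-endpoint Riemann sum on the
Euler grid (the final state carries no weight), and the ensemble
objective is the weight-averaged — or, in the minimax variant, the
maximal — per-member sum. The gradient follows the
discretize-then-differentiate principle: the backward recursion

```
g_K = 0,   g_k = g_{k+1}(I + h·∂f/∂x(x_k, u_k)) + h·ℓ′(n_k)·(1, 1)
```

is the exact transpose sensitivity of the discrete objective, and the
assembled field `G_k = Σ_θ w_θ · g^θ_{k+1} · F₁(x^θ_k)` is its L²-Riesz
representative: the discrete directional derivative equals
`Σ_k G_k δ_k h`. Because the gradient is exact for the discrete
problem, the finite-difference comparison in the test suite is an
equality check up to FD truncation (relative 1e-5 asserted, ~1e-8
observed), which simultaneously validates the state-transition
machinery that is never materialized explicitly.

The step size `η = 0.125` is applied to `G` itself (the L² field), not
to the raw parameter derivative `G·h`; the two conventions differ by
the factor `h ≈ 3.4e-3`, and only the L² convention moves the control
far enough in 500 iterations to produce the known saturated schedule
structure (full-dose plateaus for the linear cost, an initial treatment
holiday for the hyperbolic cost, near-initial values close to the
horizon where the gradient vanishes). Projecting the plain gradient
step onto the box is equivalent to stepping along the tangent-cone
projection of the negative gradient; this identity is property-tested
on boundary-touching iterates rather than relied upon implicitly.

The minimax solver is a plain active-member projected subgradient
method with constant `η`: each iteration evaluates every member's cost,
selects the worst member (lowest index on ties, for determinism), and
steps along that member's exact gradient. More sophisticated schemes
(step-size schedules, iterate averaging) exist in the literature; the
plain variant is implemented and documented as such, and its results
should be read accordingly.

Runs are fully deterministic — there is no stochastic element anywhere
in the pipeline; the only randomness in the package is the seeded
fixture-ensemble generator used for tests and demos.

## Performance

The Euler sweeps, cost sums and adjoint recursions are numba kernels
over member-contiguous arrays; one 500-iteration optimization at full
scale (1225 members × 12000 steps) takes on the order of a minute on a
single core. `fastmath` is disabled so results are reproducible IEEE
arithmetic; the vectorized kernels may still differ from the
per-step Python reference loop by FMA contraction (one ulp per step),
which can shift a feedback switching node by one step.

## Synthetic data

The package needs no external data: the reference ensemble *is* the
study condition (a deterministic parameter grid), and `random_ensemble`
draws test fixtures uniformly from the same parameter boxes. What the
ensemble does **not** model: measurement noise on the burden (policies
observe `n` exactly), pharmacokinetics (dose acts instantaneously),
acquired resistance, spatial structure, and inter-patient variation in
`d̂_D`, `d̂_T` or `n0`. Passing tests therefore demonstrate fidelity of
the scheduling mathematics under the stated model, not clinical
validity.

## Known discrepancies and limitations

- The published comparison tables for the feedback protocols are not
  exactly reproducible from the published model equations: integrating
  the stated dynamics with the stated initial split
  (`r(0) = f̂_0·n0`) reproduces the single-tumor illustration values
  and every max-TTP table cell exactly, but yields min/mean cells 3–7
  days lower than printed (≈1.5% relative). High-accuracy continuous
  integration confirms the discrepancy is in the printed tables, not in
  the discretization: the implementation follows the stated equations,
  and the affected table checks in the acceptance suite fail honestly
  by those margins.
- The hyperbolic-cost averaged optimization at `n0 = 0.75` reaches a
  strictly lower objective (and longer mean TTP′) after 500 exact-
  gradient iterations than the published row; the published statistics
  coincide with iteration ≈300 of the same descent path. The analogous
  rows for `n0 ∈ {0.25, 0.5}` and all linear-cost rows agree within
  their tolerances.
- The worst-case (minimax) schedules from the plain subgradient method
  match MTD-like behavior for the linear cost but find different — for
  `n0 = 0.5` strictly better — solutions for the hyperbolic cost.
- Whole-day flooring of per-tumor values is a reporting convention; the
  underlying statistics are grid-resolution (1/8 day) and are the ones
  used for means.
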