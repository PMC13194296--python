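"""Discrete adjoints, projections, and projected (sub)gradient descent.

The gradient machinery follows the discretize-then-differentiate
principle: the adjoint recursion is the exact transpose sensitivity of
the explicit-Euler scheme combined with left-endpoint quadrature, so
the assembled gradient is the exact derivative of the discrete
objective (finite differences agree to round-off, not merely to
discretization order).

With the admissible set ``U = {u : 0 <= u(τ) <= 1}``, projected
gradient descent ``u ← Π_U[u - η·∇J]`` needs no tangent-cone projection
of the direction: projecting the plain gradient step is equivalent
(verified as a property test).  The worst-case (minimax) objective is
minimized with a subgradient-style variant that, at each iteration,
steps along the gradient of the currently worst ensemble member.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import _kernels
from .model import (
    DEFAULT_STEP,
    EnsembleMeasure,
    InvalidParameterError,
    ThetaTwoPop,
)
from .objective import CostSpec, ell_prime
from .simulate import ControlGrid, TrajectoryBundle, n_steps_for, simulate_ensemble

__all__ = [
    "AdjointBundle",
    "GradientField",
    "OptimizerRun",
    "solve_adjoint",
    "gradient",
    "project_to_admissible",
    "project_to_tangent_cone",
    "projected_gradient_descent",
    "minimax_subgradient",
]


@dataclass
class AdjointBundle:
    """Backward adjoint path for one ensemble member.

    ``g`` has shape ``(K+1, 2)`` (row-vector adjoints ``(g_s, g_r)``
    per node); the terminal value is identically zero because the
    objective carries no terminal cost and the left quadrature rule
    gives the final state no weight.
    """

    times: np.ndarray
    g: np.ndarray
    theta: ThetaTwoPop


@dataclass
class GradientField:
    """Per-step gradient values on the control grid.

    ``values[k]`` is the L²-Riesz representative of the objective's
    differential: the discrete directional derivative along a
    perturbation ``δ`` equals ``Σ_k values[k]·δ_k·h``.
    """

    values: np.ndarray
    step: float


def solve_adjoint(
    control: ControlGrid, theta: ThetaTwoPop, cost: CostSpec
) -> AdjointBundle:
    """Solve the discrete backward adjoint equation for a single member.

    With forward states ``x_k`` from the Euler sweep, the recursion is
    ``g_K = 0`` and
    ``g_k = g_{k+1}·(I + h·∂f/∂x(x_k, u_k)) + h·ℓ'(n_k)·(1, 1)``.
    """
    from .simulate import simulate_open_loop

    traj = simulate_open_loop(theta, control)
    s = traj.s[:, 0]
    r = traj.r[:, 0]
    u = control.values
    h = control.step
    K = len(u)
    g = np.zeros((K + 1, 2))
    dD, dT, rR = theta.d_hat_D, theta.d_hat_T, theta.r_hat_R
    for k in range(K - 1, -1, -1):
        sk, rk = s[k], r[k]
        cD = 1.0 - dD * u[k]
        a11 = cD * (1.0 - 2.0 * sk - rk) - dT
        a12 = -cD * sk
        a21 = -rR * rk
        a22 = rR * (1.0 - sk - 2.0 * rk) - dT
        lp = ell_prime(cost.kind, sk + rk, cost.n0)
        gs, gr = g[k + 1]
        g[k, 0] = gs + h * (gs * a11 + gr * a21) + h * lp
        g[k, 1] = gr + h * (gs * a12 + gr * a22) + h * lp
    if not np.all(np.isfinite(g)):
        raise FloatingPointError("non-finite adjoint")
    return AdjointBundle(control.times, g, theta)


def gradient(
    control: ControlGrid, ensemble: EnsembleMeasure, cost: CostSpec
) -> GradientField:
    """Weighted ensemble gradient of the averaged objective.

    Assembles ``G_k = Σ_i w_i·g^i_{k+1}·F1(x^i_k)`` from the vectorized
    forward sweep and the discrete adjoint recursion.
    """
    a = ensemble.arrays()
    N = len(ensemble)
    u = control.values
    K = len(u)
    h = control.step
    S = np.empty((K + 1, N))
    R = np.empty((K + 1, N))
    bounds = np.empty((3, N))
    _kernels.forward_open_loop(
        a["s0"], a["r0"], a["d_hat_D"], a["d_hat_T"], a["r_hat_R"], u, h, S, R, bounds
    )
    G = np.empty(K)
    _kernels.adjoint_gradient(
        S, R, u, ensemble.weights, a["d_hat_D"], a["d_hat_T"], a["r_hat_R"],
        cost.code, cost.n0, h, G,
    )
    if not np.all(np.isfinite(G)):
        raise FloatingPointError("non-finite gradient")
    return GradientField(G, h)


def project_to_admissible(v):
    """Pointwise projection onto the admissible box ``[0, 1]``."""
    if isinstance(v, ControlGrid):
        return v  # already admissible by construction
    return np.clip(np.asarray(v, dtype=float), 0.0, 1.0)


def project_to_tangent_cone(v: np.ndarray, control: ControlGrid | np.ndarray) -> np.ndarray:
    """Projection onto the tangent cone of the box at ``control``.

    Where the control sits exactly on the lower bound only outward
    (negative) components are removed; on the upper bound only inward
    (negative) components survive; in the interior the identity.
    """
    v = np.asarray(v, dtype=float)
    u = control.values if isinstance(control, ControlGrid) else np.asarray(control, dtype=float)
    if v.shape != u.shape:
        raise InvalidParameterError("direction and control must share the grid")
    out = v.copy()
    at_lower = u == 0.0
    at_upper = u == 1.0
    out[at_lower] = np.maximum(v[at_lower], 0.0)
    out[at_upper] = np.minimum(v[at_upper], 0.0)
    return out


@dataclass
class OptimizerRun:
    """Record of a deterministic projected-(sub)gradient run."""

    control: ControlGrid
    objective_history: np.ndarray
    settings: dict
    mode: str
    controls_history: list[np.ndarray] = field(default_factory=list)
    active_theta: np.ndarray | None = None

    @property
    def final_value(self) -> float:
        return float(self.objective_history[-1])


def _initial_control(
    u_init: ControlGrid | np.ndarray | float | None,
    horizon: float | None,
    step: float,
) -> ControlGrid:
    if isinstance(u_init, ControlGrid):
        return u_init
    if horizon is None:
        raise InvalidParameterError("a horizon is required unless u_init is a ControlGrid")
    if u_init is None:
        u_init = 0.5  # unbiased: equidistant from full dose and no dose
    if np.isscalar(u_init):
        return ControlGrid.constant(float(u_init), horizon, step)
    return ControlGrid.from_values(np.asarray(u_init, dtype=float), step)


def projected_gradient_descent(
    ensemble: EnsembleMeasure,
    cost: CostSpec,
    eta: float = 0.125,
    iterations: int = 500,
    u_init: ControlGrid | np.ndarray | float | None = None,
    horizon: float | None = None,
    step: float = DEFAULT_STEP,
    store_iterates: bool = False,
    progress: Callable[[int, float], None] | None = None,
) -> OptimizerRun:
    """Minimize the averaged ensemble objective by projected gradient descent.

    Iterates ``u ← Π_U[u - η·G]`` with the exact discrete gradient
    ``G``; the run is fully deterministic.  The objective history has
    one entry per iterate (``iterations + 1`` values).
    """
    if eta <= 0:
        raise InvalidParameterError("eta must be positive")
    control = _initial_control(u_init, horizon, step)
    a = ensemble.arrays()
    N = len(ensemble)
    u = control.values.copy()
    K = len(u)
    h = control.step
    S = np.empty((K + 1, N))
    R = np.empty((K + 1, N))
    bounds = np.empty((3, N))
    G = np.empty(K)
    w = ensemble.weights
    history = np.empty(iterations + 1)
    iterates: list[np.ndarray] = []

    for it in range(iterations):
        _kernels.forward_open_loop(
            a["s0"], a["r0"], a["d_hat_D"], a["d_hat_T"], a["r_hat_R"], u, h, S, R, bounds
        )
        per_theta = _kernels.per_theta_cost(S, R, cost.code, cost.n0, h)
        history[it] = w @ per_theta
        if not np.isfinite(history[it]):
            raise FloatingPointError(
                f"non-finite objective at iteration {it}; iterate: {u!r}"
            )
        _kernels.adjoint_gradient(
            S, R, u, w, a["d_hat_D"], a["d_hat_T"], a["r_hat_R"],
            cost.code, cost.n0, h, G,
        )
        if store_iterates:
            iterates.append(u.copy())
        u = np.clip(u - eta * G, 0.0, 1.0)
        if progress is not None:
            progress(it, float(history[it]))

    _kernels.forward_open_loop(
        a["s0"], a["r0"], a["d_hat_D"], a["d_hat_T"], a["r_hat_R"], u, h, S, R, bounds
    )
    history[iterations] = w @ _kernels.per_theta_cost(S, R, cost.code, cost.n0, h)
    if store_iterates:
        iterates.append(u.copy())
    final = ControlGrid(control.times, u)
    settings = {
        "cost": cost.kind,
        "n0": cost.n0,
        "mode": "averaged",
        "eta": eta,
        "iterations": iterations,
        "step": h,
        "horizon": final.horizon,
    }
    return OptimizerRun(final, history, settings, "averaged", iterates)


def minimax_subgradient(
    ensemble: EnsembleMeasure,
    cost: CostSpec,
    eta: float = 0.125,
    iterations: int = 500,
    u_init: ControlGrid | np.ndarray | float | None = None,
    horizon: float | None = None,
    step: float = DEFAULT_STEP,
    store_iterates: bool = False,
    progress: Callable[[int, float], None] | None = None,
) -> OptimizerRun:
    """Minimize the worst-case ensemble objective.

    Each iteration evaluates every member's cost, identifies the member
    attaining the maximum (ties broken by lowest support index), and
    applies a projected gradient step for that member's individual
    cost.  A constant step size ``η`` is used throughout.
    """
    if eta <= 0:
        raise InvalidParameterError("eta must be positive")
    control = _initial_control(u_init, horizon, step)
    a = ensemble.arrays()
    u = control.values.copy()
    K = len(u)
    h = control.step
    S1 = np.empty((K + 1, 1))
    R1 = np.empty((K + 1, 1))
    bounds1 = np.empty((3, 1))
    G = np.empty(K)
    one = np.ones(1)
    history = np.empty(iterations + 1)
    active = np.empty(iterations, dtype=np.int64)
    iterates: list[np.ndarray] = []

    for it in range(iterations):
        costs = _kernels.forward_costs_only(
            a["s0"], a["r0"], a["d_hat_D"], a["d_hat_T"], a["r_hat_R"],
            u, h, cost.code, cost.n0,
        )
        i_star = int(np.argmax(costs))
        active[it] = i_star
        history[it] = costs[i_star]
        if not np.isfinite(history[it]):
            raise FloatingPointError(
                f"non-finite objective at iteration {it}; iterate: {u!r}"
            )
        sl = slice(i_star, i_star + 1)
        _kernels.forward_open_loop(
            a["s0"][sl], a["r0"][sl], a["d_hat_D"][sl], a["d_hat_T"][sl],
            a["r_hat_R"][sl], u, h, S1, R1, bounds1,
        )
        _kernels.adjoint_gradient(
            S1, R1, u, one, a["d_hat_D"][sl], a["d_hat_T"][sl], a["r_hat_R"][sl],
            cost.code, cost.n0, h, G,
        )
        if store_iterates:
            iterates.append(u.copy())
        u = np.clip(u - eta * G, 0.0, 1.0)
        if progress is not None:
            progress(it, float(history[it]))

    costs = _kernels.forward_costs_only(
        a["s0"], a["r0"], a["d_hat_D"], a["d_hat_T"], a["r_hat_R"],
        u, h, cost.code, cost.n0,
    )
    history[iterations] = costs.max()
    if store_iterates:
        iterates.append(u.copy())
    final = ControlGrid(control.times, u)
    settings = {
        "cost": cost.kind,
        "n0": cost.n0,
        "mode": "minimax",
        "eta": eta,
        "iterations": iterations,
        "step": h,
        "horizon": final.horizon,
    }
    return OptimizerRun(final, history, settings, "minimax", iterates, active)
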