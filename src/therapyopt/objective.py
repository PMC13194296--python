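"""Integral costs and ensemble objective functionals.

Two running costs of the normalized burden ``n`` are provided, both
vanishing at the baseline burden ``n0``:

* linear — ``ℓ¹(n) = n - n0``, symmetric: shrinking the tumor is
  rewarded exactly as much as growth is penalized;
* hyperbolic — ``ℓ²(n) = sqrt(1 + (n-n0)²) - 1 + (n-n0)``, asymmetric:
  growth beyond ``n0`` is penalized at slope → 2 while shrinkage earns
  a reward that saturates, reflecting the aim of stabilizing rather
  than eradicating the tumor.

The ensemble functional integrates the running cost along each member's
trajectory (left-endpoint Riemann sum on the Euler grid, so the final
node carries no weight) and either averages the per-member values with
the ensemble weights or takes their maximum (worst case).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .model import EnsembleMeasure, InvalidParameterError
from .simulate import ControlGrid, simulate_ensemble

__all__ = ["CostSpec", "FunctionalValue", "ell", "ell_prime", "evaluate_functional"]

_KIND_CODES = {"linear": _kernels.COST_LINEAR, "hyperbolic": _kernels.COST_HYPERBOLIC}


@dataclass(frozen=True)
class CostSpec:
    """Running-cost choice: ``kind`` in {"linear", "hyperbolic"} and the
    reference burden ``n0``."""

    kind: str
    n0: float

    def __post_init__(self) -> None:
        if self.kind not in _KIND_CODES:
            raise InvalidParameterError(f"unknown cost kind {self.kind!r}")
        if not 0.0 < self.n0 < 1.0:
            raise InvalidParameterError(f"n0 must lie in (0, 1), got {self.n0!r}")

    @property
    def code(self) -> int:
        return _KIND_CODES[self.kind]


def ell(kind: str, n, n0: float):
    """Running cost ``ℓ(n)``; vectorized over ``n``."""
    n = np.asarray(n, dtype=float)
    d = n - n0
    if kind == "linear":
        out = d
    elif kind == "hyperbolic":
        out = np.sqrt(1.0 + d * d) - 1.0 + d
    else:
        raise InvalidParameterError(f"unknown cost kind {kind!r}")
    return out if out.ndim else float(out)


def ell_prime(kind: str, n, n0: float):
    """Derivative ``ℓ'(n)``; vectorized over ``n``."""
    n = np.asarray(n, dtype=float)
    d = n - n0
    if kind == "linear":
        out = np.ones_like(d)
    elif kind == "hyperbolic":
        out = d / np.sqrt(1.0 + d * d) + 1.0
    else:
        raise InvalidParameterError(f"unknown cost kind {kind!r}")
    return out if out.ndim else float(out)


@dataclass
class FunctionalValue:
    """Value of an ensemble functional with its per-member breakdown."""

    value: float
    per_theta: np.ndarray
    mode: str
    argmax: int | None = None
    weights: np.ndarray | None = None


def evaluate_functional(
    control: ControlGrid | np.ndarray,
    ensemble: EnsembleMeasure,
    cost: CostSpec,
    mode: str = "averaged",
) -> FunctionalValue:
    """Evaluate the averaged or worst-case ensemble objective.

    Per-member contribution: ``h·Σ_{k<K} ℓ(n_k)`` along the Euler
    trajectory under ``control``.  ``mode="averaged"`` returns the
    weight-weighted sum; ``mode="minimax"`` returns the maximum
    contribution and records which member attains it (lowest index on
    ties).

    Controls outside ``[0, 1]`` are clamped with a warning.
    """
    if mode not in ("averaged", "minimax"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    if not isinstance(control, ControlGrid):
        values = np.asarray(control, dtype=float)
        if np.any(values < 0.0) or np.any(values > 1.0):
            warnings.warn("control outside [0, 1]; projecting onto the admissible box")
            values = np.clip(values, 0.0, 1.0)
        control = ControlGrid.from_values(values)
    traj = simulate_ensemble(ensemble, control)
    per_theta = _kernels.per_theta_cost(traj.s, traj.r, cost.code, cost.n0, control.step)
    if mode == "averaged":
        value = float(ensemble.weights @ per_theta)
        argmax = None
    else:
        argmax = int(np.argmax(per_theta))
        value = float(per_theta[argmax])
    return FunctionalValue(value, per_theta, mode, argmax, ensemble.weights)
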