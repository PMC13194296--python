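"""Tumor population models under dosing control.

Two levels of description are provided:

* a general n-species Lotka--Volterra competition model with logistic
  growth, per-species drug kill, turnover, and (optional) inter-species
  transition matrices, written in control-affine form
  ``dX/dt = F0(X) + F1(X)·D`` with the dose ``D ∈ [0, D_max]``;
* the non-dimensional two-population (drug-sensitive / drug-resistant)
  specialization obtained by rescaling time with the sensitive
  proliferation rate ``r_S`` and populations with the carrying capacity
  ``K``.  Its parameters are collected in :class:`ThetaTwoPop`.

Uncertainty over the two-population parameters is represented by a
discrete probability measure (:class:`EnsembleMeasure`): a finite set of
parameter tuples with probability weights.  A single dosing schedule is
then evaluated (or optimized) simultaneously on every member.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "InvalidParameterError",
    "InvalidStateError",
    "SimplexGuardError",
    "ThetaTwoPop",
    "GeneralModelSpec",
    "EnsembleMeasure",
    "nondimensionalize",
    "rhs_two_pop",
    "rhs_general",
    "prostate_grid_ensemble",
    "random_ensemble",
    "DEFAULT_R_S",
    "DEFAULT_STEP",
]

#: Proliferation rate of drug-sensitive prostate-cancer cells (day^-1),
#: the literature estimate used for time normalization.
DEFAULT_R_S: float = 0.027

#: Default Euler step in normalized time: r_S/8, i.e. 8 nodes per day.
DEFAULT_STEP: float = DEFAULT_R_S / 8.0


class InvalidParameterError(ValueError):
    """A model parameter violates its admissibility constraints."""


class InvalidStateError(ValueError):
    """A state vector is non-finite or structurally invalid."""


class SimplexGuardError(RuntimeError):
    """A trajectory left the inflated invariant simplex.

    For admissible controls the population simplex is invariant, so this
    guard firing indicates a bug or an inadmissible input rather than a
    legitimate model regime.
    """


@dataclass(frozen=True)
class ThetaTwoPop:
    """Non-dimensional parameters of the two-population model.

    Parameters
    ----------
    d_hat_D:
        Rescaled drug sensitivity of the sensitive clone (dimensionless,
        twice the dimensional kill coefficient).
    d_hat_T:
        Turnover (death) rate relative to the sensitive proliferation
        rate (dimensionless).
    r_hat_R:
        Proliferation rate of resistant cells relative to sensitive
        cells (dimensionless).
    f_hat_0:
        Initial fraction of resistant cells, in ``[0, 1]``.
    n0:
        Initial total tumor burden as a fraction of carrying capacity,
        in ``(0, 1)``.
    """

    d_hat_D: float
    d_hat_T: float
    r_hat_R: float
    f_hat_0: float
    n0: float

    def __post_init__(self) -> None:
        for name in ("d_hat_D", "d_hat_T", "r_hat_R", "f_hat_0", "n0"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidParameterError(f"{name} must be finite and >= 0, got {v!r}")
        if not 0.0 <= self.f_hat_0 <= 1.0:
            raise InvalidParameterError(f"f_hat_0 must lie in [0, 1], got {self.f_hat_0!r}")
        if not 0.0 < self.n0 < 1.0:
            raise InvalidParameterError(f"n0 must lie in (0, 1), got {self.n0!r}")

    @property
    def initial_state(self) -> tuple[float, float]:
        """Cauchy datum ``(s(0), r(0)) = ((1-f̂0)·n0, f̂0·n0)``."""
        return ((1.0 - self.f_hat_0) * self.n0, self.f_hat_0 * self.n0)

    def astuple(self) -> tuple[float, float, float, float, float]:
        return (self.d_hat_D, self.d_hat_T, self.r_hat_R, self.f_hat_0, self.n0)


def nondimensionalize(
    r_S: float,
    r_R: float,
    d_D: float,
    d_T: float,
    K: float,
    S0: float,
    R0: float,
    T_hor: float,
) -> tuple[ThetaTwoPop, float]:
    """Rescale the dimensional two-population model to dimensionless form.

    Time is rescaled by the sensitive proliferation rate (``τ = r_S·t``)
    and populations by the carrying capacity ``K``.

    Parameters
    ----------
    r_S, r_R:
        Proliferation rates of sensitive and resistant cells (time⁻¹).
    d_D:
        Drug sensitivity coefficient (dimensionless); the rescaled
        parameter is ``d̂_D = 2·d_D``.
    d_T:
        Turnover rate (time⁻¹).
    K:
        Carrying capacity (cells).
    S0, R0:
        Initial sensitive / resistant populations (cells).
    T_hor:
        Time horizon in the original time units (days).

    Returns
    -------
    (theta, T):
        The dimensionless parameter tuple and the normalized horizon
        ``T = T_hor·r_S``.
    """
    if r_S <= 0 or K <= 0:
        raise InvalidParameterError("r_S and K must be positive")
    if S0 < 0 or R0 < 0 or S0 + R0 > K:
        raise InvalidParameterError("need S0, R0 >= 0 and S0 + R0 <= K")
    total = S0 + R0
    if total == 0:
        raise InvalidParameterError("initial population must be positive")
    theta = ThetaTwoPop(
        d_hat_D=2.0 * d_D,
        d_hat_T=d_T / r_S,
        r_hat_R=r_R / r_S,
        f_hat_0=R0 / total,
        n0=total / K,
    )
    return theta, T_hor * r_S


def rhs_two_pop(
    state: tuple[float, float] | np.ndarray,
    u: float,
    theta: ThetaTwoPop,
) -> tuple[float, float]:
    """Right-hand side of the non-dimensional two-population dynamics.

    ``ds/dτ = (1-s-r)(1-d̂_D·u)·s - d̂_T·s`` and
    ``dr/dτ = r̂_R·(1-s-r)·r - d̂_T·r``; the resistant clone is fully
    insensitive to the drug, which acts by flipping the sign of the
    sensitive clone's effective growth whenever ``d̂_D·u > 1``.
    """
    s, r = float(state[0]), float(state[1])
    if not (np.isfinite(s) and np.isfinite(r)):
        raise InvalidStateError(f"non-finite state ({s!r}, {r!r})")
    free = 1.0 - s - r
    ds = free * (1.0 - theta.d_hat_D * u) * s - theta.d_hat_T * s
    dr = theta.r_hat_R * free * r - theta.d_hat_T * r
    return (ds, dr)


# --------------------------------------------------------------------------
# General n-species model
# --------------------------------------------------------------------------

@dataclass
class GeneralModelSpec:
    """Parameters of the dimensional n-species competition model.

    The dynamics are control-affine in the dose ``D``:

    ``dX_i/dt = r_i(1-ΣX/K)X_i - d_i^T X_i + Σ_j A_ij X_j
               + [-r_i(1-ΣX/K)(2 d_i^I/D_max) X_i + Σ_j (A^I_ij/D_max) X_j]·D``

    The transition matrices ``A`` (spontaneous) and ``A_I``
    (drug-induced) must have zero column sums so that inter-species
    evolution conserves total population.
    """

    n_species: int
    r: np.ndarray
    K: float
    d_I: np.ndarray
    d_T: np.ndarray
    A: np.ndarray
    A_I: np.ndarray
    f: np.ndarray
    N0: float
    D_max: float = 1.0
    K_min: float | None = None
    K_max: float | None = None

    def __post_init__(self) -> None:
        n = self.n_species
        self.r = np.asarray(self.r, dtype=float)
        self.d_I = np.asarray(self.d_I, dtype=float)
        self.d_T = np.asarray(self.d_T, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.A_I = np.asarray(self.A_I, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        # Single-K ensembles by default: the invariant-simplex bound
        # coincides with the carrying capacity.
        if self.K_min is None:
            self.K_min = self.K
        if self.K_max is None:
            self.K_max = self.K
        self.validate()

    def validate(self) -> None:
        n = self.n_species
        if n < 1:
            raise InvalidParameterError("n_species must be a positive integer")
        for name, arr, shape in (
            ("r", self.r, (n,)),
            ("d_I", self.d_I, (n,)),
            ("d_T", self.d_T, (n,)),
            ("f", self.f, (n,)),
            ("A", self.A, (n, n)),
            ("A_I", self.A_I, (n, n)),
        ):
            if arr.shape != shape:
                raise InvalidParameterError(f"{name} must have shape {shape}, got {arr.shape}")
        if np.any(self.r <= 0):
            raise InvalidParameterError("proliferation rates r must be positive")
        if np.any(self.d_I < 0):
            raise InvalidParameterError("drug sensitivities d_I must be >= 0")
        if np.any(self.d_T < 0):
            raise InvalidParameterError("turnover rates d_T must be >= 0")
        for name, M in (("A", self.A), ("A_I", self.A_I)):
            off = M - np.diag(np.diag(M))
            if np.any(off < 0):
                raise InvalidParameterError(f"off-diagonal entries of {name} must be >= 0")
            if np.any(np.diag(M) > 0):
                raise InvalidParameterError(f"diagonal entries of {name} must be <= 0")
            colsum = M.sum(axis=0)
            if np.any(np.abs(colsum) > 1e-10 * max(1.0, np.abs(M).max())):
                raise InvalidParameterError(f"columns of {name} must sum to 0 (got {colsum})")
        if np.any(self.f < 0) or abs(self.f.sum() - 1.0) > 1e-10:
            raise InvalidParameterError("initial fractions f must be >= 0 and sum to 1")
        if not 0.0 <= self.N0 <= self.K:
            raise InvalidParameterError("initial population N0 must lie in [0, K]")
        if self.D_max <= 0:
            raise InvalidParameterError("D_max must be positive")
        if not self.K_min <= self.K <= self.K_max:
            raise InvalidParameterError("carrying capacity K must lie in [K_min, K_max]")

    @property
    def initial_state(self) -> np.ndarray:
        return self.f * self.N0


def rhs_general(X: np.ndarray, D: float, spec: GeneralModelSpec) -> np.ndarray:
    """Control-affine right-hand side ``F0(X) + F1(X)·D`` of the n-species model.

    Raises
    ------
    SimplexGuardError
        If ``‖X‖ > 2·K_max``.  For admissible doses the population
        simplex is invariant, so states this far out are unreachable;
        the guard replaces the smooth cut-off used in the analysis.
    """
    X = np.asarray(X, dtype=float)
    if X.shape != (spec.n_species,):
        raise InvalidStateError(f"state must have shape ({spec.n_species},)")
    if not np.all(np.isfinite(X)):
        raise InvalidStateError("non-finite state")
    if np.linalg.norm(X) > 2.0 * spec.K_max:
        raise SimplexGuardError(
            f"state norm {np.linalg.norm(X):.3g} exceeds guard radius {2.0 * spec.K_max:.3g}"
        )
    if not 0.0 <= D <= spec.D_max:
        raise InvalidParameterError(f"dose must lie in [0, D_max], got {D!r}")
    free = 1.0 - X.sum() / spec.K
    F0 = spec.r * free * X - spec.d_T * X + spec.A @ X
    F1 = -spec.r * free * (2.0 * spec.d_I / spec.D_max) * X + (spec.A_I / spec.D_max) @ X
    return F0 + F1 * D


# --------------------------------------------------------------------------
# Ensembles
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EnsembleMeasure:
    """Finite weighted family of two-population parameter tuples.

    Represents a discrete probability measure on parameter space: the
    ``support`` lists the parameter tuples and ``weights`` their
    probabilities (non-negative, summing to one).
    """

    support: tuple[ThetaTwoPop, ...]
    weights: np.ndarray

    def __init__(self, support: Sequence[ThetaTwoPop], weights: Iterable[float] | None = None):
        support = tuple(support)
        if len(support) == 0:
            raise InvalidParameterError("ensemble support must be non-empty")
        if weights is None:
            w = np.full(len(support), 1.0 / len(support))
        else:
            w = np.asarray(list(weights), dtype=float)
        if w.shape != (len(support),):
            raise InvalidParameterError("weights must match the support length")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise InvalidParameterError("weights must be >= 0 and sum to 1 within 1e-12")
        seen = set()
        for th in support:
            key = th.astuple()
            if key in seen:
                raise InvalidParameterError(f"duplicate support point {key}")
            seen.add(key)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return len(self.support)

    def __iter__(self) -> Iterator[ThetaTwoPop]:
        return iter(self.support)

    def arrays(self) -> dict[str, np.ndarray]:
        """Column-wise view of the support for vectorized integration."""
        cols = np.array([th.astuple() for th in self.support], dtype=float)
        d_hat_D, d_hat_T, r_hat_R, f_hat_0, n0 = cols.T
        return {
            "d_hat_D": np.ascontiguousarray(d_hat_D),
            "d_hat_T": np.ascontiguousarray(d_hat_T),
            "r_hat_R": np.ascontiguousarray(r_hat_R),
            "f_hat_0": np.ascontiguousarray(f_hat_0),
            "n0": np.ascontiguousarray(n0),
            "s0": np.ascontiguousarray((1.0 - f_hat_0) * n0),
            "r0": np.ascontiguousarray(f_hat_0 * n0),
        }

    @classmethod
    def singleton(cls, theta: ThetaTwoPop) -> "EnsembleMeasure":
        return cls((theta,), (1.0,))


#: Grid resolution of the reference prostate-cancer ensemble.
GRID_R_HAT_R = np.linspace(0.5, 1.0, 25)
GRID_F_HAT_0 = np.linspace(0.002, 0.1, 49)


def prostate_grid_ensemble(n0: float) -> EnsembleMeasure:
    """Uniform product-grid ensemble for prostate cancer under ADT.

    The effectiveness and turnover parameters are fixed at the
    literature point estimates (``d̂_D = 1.5``, ``d̂_T = 0``, the most
    adverse turnover scenario), while the uncertain relative resistant
    proliferation ``r̂_R ∈ [0.5, 1]`` (25 nodes) and initial resistant
    fraction ``f̂_0 ∈ [0.002, 0.1]`` (49 nodes) are discretized on a
    uniform 1225-point product grid with equal weights.

    Parameters
    ----------
    n0:
        Initial normalized tumor burden, shared by every member.  The
        reference experiments use ``n0 ∈ {0.25, 0.50, 0.75}``; other
        values are accepted with a warning.
    """
    if n0 not in (0.25, 0.50, 0.75):
        warnings.warn(
            f"n0={n0!r} is outside the reference set {{0.25, 0.5, 0.75}}",
            stacklevel=2,
        )
    support = [
        ThetaTwoPop(1.5, 0.0, float(rr), float(f0), n0)
        for rr in GRID_R_HAT_R
        for f0 in GRID_F_HAT_0
    ]
    return EnsembleMeasure(support)


def random_ensemble(n: int, seed: int, n0: float = 0.5) -> EnsembleMeasure:
    """Random ensemble drawn uniformly from the reference parameter boxes.

    Useful as a test fixture: ``d̂_D = 1.5`` and ``d̂_T = 0`` are held
    fixed while ``r̂_R ~ U[0.5, 1]`` and ``f̂_0 ~ U[0.002, 0.1]``.
    Deterministic given ``seed``.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    rr = rng.uniform(0.5, 1.0, size=n)
    f0 = rng.uniform(0.002, 0.1, size=n)
    support = [ThetaTwoPop(1.5, 0.0, float(a), float(b), n0) for a, b in zip(rr, f0)]
    return EnsembleMeasure(support)
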