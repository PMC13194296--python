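"""Numba kernels for vectorized ensemble integration and adjoints.

All kernels share the same layout: states are stored time-major,
``S[k, i]`` = sensitive burden of ensemble member ``i`` at Euler node
``k``, so the inner loop over members is contiguous and vectorizes.
The explicit-Euler recursion and the discrete adjoint below are exact
transposes of one another: the adjoint differentiates the discretized
scheme, not the continuous equations.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: Cost-kind codes shared with :mod:`therapyopt.objective`.
COST_LINEAR = 1
COST_HYPERBOLIC = 2

#: Policy mode codes.
MODE_TREAT = 1
MODE_VACATION = 0


@njit(cache=True)
def forward_open_loop(s0, r0, dD, dT, rR, u, h, S, R, bounds):
    """Euler sweep under a shared open-loop control.

    Fills ``S``/``R`` of shape ``(K+1, N)`` and writes per-member
    ``(min s, min r, max n)`` into ``bounds`` of shape ``(3, N)`` for
    the simplex guard.
    """
    N = s0.shape[0]
    K = u.shape[0]
    for i in range(N):
        S[0, i] = s0[i]
        R[0, i] = r0[i]
        bounds[0, i] = s0[i]
        bounds[1, i] = r0[i]
        bounds[2, i] = s0[i] + r0[i]
    for k in range(K):
        uk = u[k]
        for i in range(N):
            s = S[k, i]
            r = R[k, i]
            free = 1.0 - s - r
            sn = s + h * (free * (1.0 - dD[i] * uk) * s - dT[i] * s)
            rn = r + h * (rR[i] * free * r - dT[i] * r)
            S[k + 1, i] = sn
            R[k + 1, i] = rn
            if sn < bounds[0, i]:
                bounds[0, i] = sn
            if rn < bounds[1, i]:
                bounds[1, i] = rn
            if sn + rn > bounds[2, i]:
                bounds[2, i] = sn + rn


@njit(cache=True)
def forward_threshold_policy(
    s0, r0, dD, dT, rR, init_mode, lower, upper, h, K, S, R, U, bounds,
    decide_every,
):
    """Euler sweep under a two-threshold bang-bang feedback policy.

    Each member carries its own controller mode: in TREAT mode the
    policy emits ``u = 1`` and switches to VACATION when the observed
    burden ``n`` drops to ``lower`` (inclusive); in VACATION mode it
    emits ``u = 0`` and switches to TREAT when ``n`` reaches ``upper``
    (inclusive).  The rule is re-evaluated every ``decide_every`` Euler
    nodes (1 = continuously), and the realized per-member control is
    recorded in ``U`` of shape ``(K, N)``.
    """
    N = s0.shape[0]
    mode = np.empty(N, dtype=np.int8)
    for i in range(N):
        S[0, i] = s0[i]
        R[0, i] = r0[i]
        mode[i] = init_mode
        bounds[0, i] = s0[i]
        bounds[1, i] = r0[i]
        bounds[2, i] = s0[i] + r0[i]
    for k in range(K):
        decide = k % decide_every == 0
        for i in range(N):
            s = S[k, i]
            r = R[k, i]
            n = s + r
            if decide:
                if mode[i] == MODE_TREAT:
                    if n <= lower:
                        mode[i] = MODE_VACATION
                else:
                    if n >= upper:
                        mode[i] = MODE_TREAT
            uk = 1.0 if mode[i] == MODE_TREAT else 0.0
            U[k, i] = uk
            free = 1.0 - n
            sn = s + h * (free * (1.0 - dD[i] * uk) * s - dT[i] * s)
            rn = r + h * (rR[i] * free * r - dT[i] * r)
            S[k + 1, i] = sn
            R[k + 1, i] = rn
            if sn < bounds[0, i]:
                bounds[0, i] = sn
            if rn < bounds[1, i]:
                bounds[1, i] = rn
            if sn + rn > bounds[2, i]:
                bounds[2, i] = sn + rn


@njit(cache=True)
def per_theta_cost(S, R, kind, n0, h):
    """Left-endpoint Riemann sums ``h·Σ_{k<K} ℓ(n_k)`` per member."""
    K1, N = S.shape
    K = K1 - 1
    out = np.zeros(N)
    for k in range(K):
        for i in range(N):
            n = S[k, i] + R[k, i]
            if kind == COST_LINEAR:
                out[i] += n - n0
            else:
                d = n - n0
                out[i] += np.sqrt(1.0 + d * d) - 1.0 + d
    for i in range(N):
        out[i] *= h
    return out


@njit(cache=True)
def forward_costs_only(s0, r0, dD, dT, rR, u, h, kind, n0):
    """Open-loop sweep that accumulates per-member costs without storing paths."""
    N = s0.shape[0]
    K = u.shape[0]
    s = s0.copy()
    r = r0.copy()
    out = np.zeros(N)
    for k in range(K):
        uk = u[k]
        for i in range(N):
            si = s[i]
            ri = r[i]
            n = si + ri
            if kind == COST_LINEAR:
                out[i] += n - n0
            else:
                d = n - n0
                out[i] += np.sqrt(1.0 + d * d) - 1.0 + d
            free = 1.0 - n
            s[i] = si + h * (free * (1.0 - dD[i] * uk) * si - dT[i] * si)
            r[i] = ri + h * (rR[i] * free * ri - dT[i] * ri)
    for i in range(N):
        out[i] *= h
    return out


@njit(cache=True)
def adjoint_gradient(S, R, u, w, dD, dT, rR, kind, n0, h, G):
    """Backward adjoint sweep and weighted gradient assembly.

    Implements the exact transpose sensitivity of the Euler scheme with
    left-endpoint quadrature: with row-vector adjoints ``g_K = 0`` and

        ``g_k = g_{k+1}·(I + h·∂f/∂x(x_k, u_k)) + h·ℓ'(n_k)·(1, 1)``,

    the derivative of the discrete functional with respect to the step
    value ``u_k`` is ``h·G_k`` where
    ``G_k = Σ_i w_i · g_{k+1,s}^i · F1_s(x_k^i)`` (the controlled field
    only enters the sensitive equation).  ``G`` is therefore the
    L²-Riesz representative of the differential on the step grid.
    """
    K = u.shape[0]
    N = w.shape[0]
    gs = np.zeros(N)
    gr = np.zeros(N)
    for k in range(K - 1, -1, -1):
        uk = u[k]
        acc = 0.0
        for i in range(N):
            s = S[k, i]
            r = R[k, i]
            free = 1.0 - s - r
            # gradient uses the adjoint at node k+1 (current gs before update)
            acc += w[i] * gs[i] * (-dD[i] * free * s)
            if kind == COST_LINEAR:
                lp = 1.0
            else:
                d = s + r - n0
                lp = d / np.sqrt(1.0 + d * d) + 1.0
            cD = 1.0 - dD[i] * uk
            a11 = cD * (1.0 - 2.0 * s - r) - dT[i]
            a12 = -cD * s
            a21 = -rR[i] * r
            a22 = rR[i] * (1.0 - s - 2.0 * r) - dT[i]
            gsn = gs[i] + h * (gs[i] * a11 + gr[i] * a21) + h * lp
            grn = gr[i] + h * (gs[i] * a12 + gr[i] * a22) + h * lp
            gs[i] = gsn
            gr[i] = grn
        G[k] = acc


@njit(cache=True)
def ttp_indices(S, R, threshold):
    """First/last threshold-crossing Euler node indices per member.

    Returns ``(first, last)`` where ``first[i]`` is the smallest node
    ``k >= 1`` with ``n_k >= threshold`` (or ``-1`` if never) and
    ``last[i]`` the largest node with ``n_k <= threshold``.
    """
    K1, N = S.shape
    first = np.full(N, -1, dtype=np.int64)
    last = np.zeros(N, dtype=np.int64)
    for k in range(1, K1):
        for i in range(N):
            n = S[k, i] + R[k, i]
            if n >= threshold:
                if first[i] < 0:
                    first[i] = k
            if n <= threshold:
                last[i] = k
    return first, last
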