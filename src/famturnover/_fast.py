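"""Numba-compiled kernels for the pruning likelihood.

The public API lives in :mod:`famturnover.likelihood`; these kernels exist so
that the multi-restart maximum-likelihood fits inside the simulation
experiments run in reasonable time.  ``likelihood.family_loglik`` is the
plain-numpy reference implementation and the test suite asserts the two
agree to near machine precision.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["fill_transition_matrix", "prune_loglik", "loglik_kernel"]


@njit(cache=True)
def fill_transition_matrix(P, t, beta, delta, N):  # pragma: no cover - compiled
    """Exact linear-BD transition matrix over states ``0..N`` (row = start).

    Rows are built by iterated convolution of the single-lineage offspring
    distribution: P(0) = alpha, P(k >= 1) = (1-alpha)(1-eta) eta**(k-1).
    Truncation at ``N`` is exact entry-wise (entries ``<= N`` of an i-fold
    convolution depend only on entries ``<= N`` of the factors).
    """
    for i in range(N + 1):
        for j in range(N + 1):
            P[i, j] = 0.0
    if t == 0.0 or (beta == 0.0 and delta == 0.0):
        for i in range(N + 1):
            P[i, i] = 1.0
        return
    if beta == 0.0:
        alpha = 1.0 - np.exp(-delta * t)
        eta = 0.0
    elif delta == 0.0:
        alpha = 0.0
        eta = 1.0 - np.exp(-beta * t)
    elif beta == delta:
        alpha = beta * t / (1.0 + beta * t)
        eta = alpha
    else:
        # expm1 keeps alpha smooth through beta ~= delta (no cancellation)
        em1 = np.expm1((beta - delta) * t)
        denom = beta * em1 + (beta - delta)
        alpha = delta * em1 / denom
        eta = beta * em1 / denom
    # single-lineage distribution: p[0] = alpha, p[k>=1] = c * eta**(k-1)
    c = (1.0 - alpha) * (1.0 - eta)
    P[0, 0] = 1.0
    if N >= 1:
        P[1, 0] = alpha
        P[1, 1] = c
        for k in range(2, N + 1):
            P[1, k] = P[1, k - 1] * eta
        # row_i = conv(row_{i-1}, p); the geometric tail of p turns the
        # convolution into an O(N) recurrence per row:
        # conv[j] = alpha*a[j] + c*s[j],  s[j] = a[j-1] + eta*s[j-1]
        for i in range(2, N + 1):
            s = 0.0
            P[i, 0] = alpha * P[i - 1, 0]
            for j in range(1, N + 1):
                s = P[i - 1, j - 1] + eta * s
                P[i, j] = alpha * P[i - 1, j] + c * s


@njit(cache=True)
def prune_loglik(
    child_left,
    child_right,
    leaf_col,
    counts,
    weights,
    root_count,
    N,
    P,
    L,
):  # pragma: no cover - compiled
    """Summed pruning log-likelihood over (deduplicated, weighted) count rows.

    Nodes are in postorder with the root last; ``P[i]`` is the transition
    matrix of the branch above node ``i`` (filled by the caller, which lets
    finite-difference gradients refill only the branches whose rates
    changed).  ``L`` (M, U, N+1) is a caller workspace.  Returns
    ``sum_u weights[u] * log L_u``; impossible data yield a large negative
    penalty.
    """
    M = child_left.shape[0]
    U = counts.shape[0]
    S = N + 1
    L[:, :, :] = 0.0
    logscale = np.zeros(U)
    dead = np.zeros(U, dtype=np.uint8)
    for i in range(M):
        if child_left[i] < 0:
            for u in range(U):
                c = counts[u, leaf_col[i]]
                if c <= N:
                    L[i, u, c] = 1.0
        else:
            cl = child_left[i]
            cr = child_right[i]
            # a leaf child's partial likelihood is an indicator: its message
            # is just one column of the transition matrix
            cl_leaf = child_left[cl] < 0
            cr_leaf = child_right[cr] < 0 and child_left[cr] < 0
            for u in range(U):
                if dead[u]:
                    continue
                ccl = counts[u, leaf_col[cl]] if cl_leaf else -1
                ccr = counts[u, leaf_col[cr]] if cr_leaf else -1
                for s in range(S):
                    if cl_leaf:
                        al = P[cl, s, ccl] if ccl <= N else 0.0
                    else:
                        al = 0.0
                        for sp in range(S):
                            al += P[cl, s, sp] * L[cl, u, sp]
                    if cr_leaf:
                        ar = P[cr, s, ccr] if ccr <= N else 0.0
                    else:
                        ar = 0.0
                        for sp in range(S):
                            ar += P[cr, s, sp] * L[cr, u, sp]
                    L[i, u, s] = al * ar
                m = 0.0
                for s in range(S):
                    if L[i, u, s] > m:
                        m = L[i, u, s]
                if m <= 0.0:
                    dead[u] = 1
                elif m < 1e-200:
                    for s in range(S):
                        L[i, u, s] /= m
                    logscale[u] += np.log(m)
    total = 0.0
    for u in range(U):
        if dead[u]:
            return -1.0e12
        v = L[M - 1, u, root_count]
        if v <= 0.0:
            return -1.0e12
        total += weights[u] * (np.log(v) + logscale[u])
    return total


@njit(cache=True)
def loglik_kernel(
    beta_b,
    delta_b,
    T_b,
    child_left,
    child_right,
    leaf_col,
    counts,
    weights,
    root_count,
    N,
    P,
    L,
):  # pragma: no cover - compiled
    """Fill every branch matrix, then prune (one-shot convenience path)."""
    M = child_left.shape[0]
    for b in range(M - 1):
        fill_transition_matrix(P[b], T_b[b], beta_b[b], delta_b[b], N)
    return prune_loglik(
        child_left, child_right, leaf_col, counts, weights, root_count, N, P, L
    )
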