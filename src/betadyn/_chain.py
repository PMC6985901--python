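"""Numba kernels for the HMM chain recursions (scaled forward-backward and
log-domain Viterbi). Kept free of Python objects so the 1e5-sample envelope
fits stay fast on one CPU."""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["forward_backward", "viterbi_path"]


@njit(cache=True)
def _fb_segment(b, A, pi, gamma, xi_sum):
    """Scaled forward-backward on pre-exponentiated likelihood ratios ``b``.

    b[t, k] = exp(loglik[t, k] - max_k loglik[t, k]); A and pi may be
    sub-stochastic (exp of expected logs). Fills gamma rows, accumulates
    xi_sum, returns log of the normaliser (excluding the loglik row maxima).
    """
    T, K = b.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    s = 0.0
    for k in range(K):
        alpha[0, k] = pi[k] * b[0, k]
        s += alpha[0, k]
    c[0] = s
    for k in range(K):
        alpha[0, k] /= s
    for t in range(1, T):
        s = 0.0
        for k in range(K):
            acc = 0.0
            for j in range(K):
                acc += alpha[t - 1, j] * A[j, k]
            alpha[t, k] = acc * b[t, k]
            s += alpha[t, k]
        c[t] = s
        for k in range(K):
            alpha[t, k] /= s

    beta = np.ones(K)
    for k in range(K):
        gamma[T - 1, k] = alpha[T - 1, k]
    for t in range(T - 2, -1, -1):
        bb = np.empty(K)
        for k in range(K):
            bb[k] = b[t + 1, k] * beta[k]
        # xi contribution at transition t -> t+1
        for j in range(K):
            for k in range(K):
                xi_sum[j, k] += alpha[t, j] * A[j, k] * bb[k] / c[t + 1]
        new_beta = np.empty(K)
        g = 0.0
        for j in range(K):
            acc = 0.0
            for k in range(K):
                acc += A[j, k] * bb[k]
            new_beta[j] = acc / c[t + 1]
        for j in range(K):
            beta[j] = new_beta[j]
            gamma[t, j] = alpha[t, j] * beta[j]
            g += gamma[t, j]
        for j in range(K):
            gamma[t, j] /= g

    lnZ = 0.0
    for t in range(T):
        lnZ += np.log(c[t])
    return lnZ


def forward_backward(loglik: np.ndarray, lnA: np.ndarray, lnpi: np.ndarray,
                     boundaries) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Forward-backward over independent segments.

    ``boundaries``: segment start indices including 0, e.g. [0, n1, n1+n2].
    Returns (gamma, xi_sum, lnZ, first_counts) where first_counts sums gamma
    over segment-initial samples (for the initial-distribution update).
    """
    T, K = loglik.shape
    lstar = loglik.max(axis=1)
    b = np.exp(loglik - lstar[:, None])
    A = np.exp(lnA)
    pi = np.exp(lnpi)
    gamma = np.empty((T, K))
    xi_sum = np.zeros((K, K))
    lnZ = float(lstar.sum())
    edges = list(boundaries) + [T]
    first_counts = np.zeros(K)
    for i in range(len(edges) - 1):
        s, e = edges[i], edges[i + 1]
        if e <= s:
            continue
        lnZ += _fb_segment(b[s:e], A, pi, gamma[s:e], xi_sum)
        first_counts += gamma[s]
    return gamma, xi_sum, lnZ, first_counts


@njit(cache=True)
def _viterbi_segment(loglik, lnA, lnpi):
    T, K = loglik.shape
    delta = np.empty((T, K))
    psi = np.empty((T, K), dtype=np.int64)
    for k in range(K):
        delta[0, k] = lnpi[k] + loglik[0, k]
        psi[0, k] = 0
    for t in range(1, T):
        for k in range(K):
            best = -1e300
            arg = 0
            for j in range(K):
                v = delta[t - 1, j] + lnA[j, k]
                if v > best:
                    best = v
                    arg = j
            delta[t, k] = best + loglik[t, k]
            psi[t, k] = arg
    path = np.empty(T, dtype=np.int64)
    best = -1e300
    arg = 0
    for k in range(K):
        if delta[T - 1, k] > best:
            best = delta[T - 1, k]
            arg = k
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


def viterbi_path(loglik: np.ndarray, lnA: np.ndarray, lnpi: np.ndarray,
                 boundaries) -> np.ndarray:
    """Most probable state sequence, segment by segment (log domain)."""
    T = loglik.shape[0]
    edges = list(boundaries) + [T]
    path = np.empty(T, dtype=np.int64)
    for i in range(len(edges) - 1):
        s, e = edges[i], edges[i + 1]
        if e <= s:
            continue
        path[s:e] = _viterbi_segment(loglik[s:e], lnA, lnpi)
    return path
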