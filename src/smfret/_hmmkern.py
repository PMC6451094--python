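"""Numba kernels for Gaussian-emission HMM recursions.

Scaled forward/backward recursions (Rabiner-style normalization), the
Baum–Welch E-step sufficient statistics, and Viterbi decoding.  Kept free
of Python objects so per-molecule training over thousands of frames stays
fast enough to run on every trace.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_LOG2PI = float(np.log(2.0 * np.pi))


@njit
def emission_probs(obs, means, sds):
    T = obs.shape[0]
    N = means.shape[0]
    b = np.empty((T, N))
    for t in range(T):
        for n in range(N):
            z = (obs[t] - means[n]) / sds[n]
            b[t, n] = np.exp(-0.5 * z * z) / (sds[n] * np.sqrt(2.0 * np.pi))
            if b[t, n] < 1e-300:
                b[t, n] = 1e-300
    return b


@njit
def forward_loglik(obs, startprob, transmat, means, sds):
    """Total log-likelihood via the scaled forward recursion."""
    b = emission_probs(obs, means, sds)
    T, N = b.shape
    alpha = np.empty(N)
    tmp = np.empty(N)
    loglik = 0.0
    for n in range(N):
        alpha[n] = startprob[n] * b[0, n]
    c = alpha.sum()
    loglik += np.log(c)
    alpha /= c
    for t in range(1, T):
        for j in range(N):
            s = 0.0
            for i in range(N):
                s += alpha[i] * transmat[i, j]
            tmp[j] = s * b[t, j]
        c = tmp.sum()
        loglik += np.log(c)
        for j in range(N):
            alpha[j] = tmp[j] / c
    return loglik


@njit
def baum_welch_estep(obs, startprob, transmat, means, sds):
    """One E-step: returns (loglik, gamma, xi_sum).

    ``gamma`` is the (T, N) state posterior, ``xi_sum`` the (N, N) sum of
    pairwise transition posteriors over time.
    """
    b = emission_probs(obs, means, sds)
    T, N = b.shape
    alpha = np.empty((T, N))
    beta = np.empty((T, N))
    scale = np.empty(T)

    for n in range(N):
        alpha[0, n] = startprob[n] * b[0, n]
    scale[0] = alpha[0].sum()
    alpha[0] /= scale[0]
    for t in range(1, T):
        for j in range(N):
            s = 0.0
            for i in range(N):
                s += alpha[t - 1, i] * transmat[i, j]
            alpha[t, j] = s * b[t, j]
        scale[t] = alpha[t].sum()
        alpha[t] /= scale[t]

    for n in range(N):
        beta[T - 1, n] = 1.0
    for t in range(T - 2, -1, -1):
        for i in range(N):
            s = 0.0
            for j in range(N):
                s += transmat[i, j] * b[t + 1, j] * beta[t + 1, j]
            beta[t, i] = s / scale[t + 1]

    gamma = np.empty((T, N))
    for t in range(T):
        norm = 0.0
        for n in range(N):
            gamma[t, n] = alpha[t, n] * beta[t, n]
            norm += gamma[t, n]
        for n in range(N):
            gamma[t, n] /= norm

    xi_sum = np.zeros((N, N))
    for t in range(T - 1):
        norm = 0.0
        xi_t = np.empty((N, N))
        for i in range(N):
            for j in range(N):
                v = alpha[t, i] * transmat[i, j] * b[t + 1, j] * beta[t + 1, j]
                xi_t[i, j] = v
                norm += v
        for i in range(N):
            for j in range(N):
                xi_sum[i, j] += xi_t[i, j] / norm

    loglik = np.log(scale).sum()
    return loglik, gamma, xi_sum


@njit
def viterbi(obs, startprob, transmat, means, sds):
    """Most likely state path and its joint log-probability."""
    b = emission_probs(obs, means, sds)
    T, N = b.shape
    logb = np.log(b)
    loga = np.log(transmat + 1e-300)
    delta = np.empty((T, N))
    psi = np.empty((T, N), dtype=np.int64)
    for n in range(N):
        delta[0, n] = np.log(startprob[n] + 1e-300) + logb[0, n]
    for t in range(1, T):
        for j in range(N):
            best = -1e308
            arg = 0
            for i in range(N):
                v = delta[t - 1, i] + loga[i, j]
                if v > best:
                    best = v
                    arg = i
            delta[t, j] = best + logb[t, j]
            psi[t, j] = arg
    path = np.empty(T, dtype=np.int64)
    best = -1e308
    for n in range(N):
        if delta[T - 1, n] > best:
            best = delta[T - 1, n]
            path[T - 1] = n
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path, best
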