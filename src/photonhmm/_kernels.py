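"""Numerical kernels for photon-by-photon HMM inference.

Sequences (one per burst) are stored concatenated in a single int8 color
array with an offsets vector, so the whole dataset is traversed in one
compiled pass.  Forward/backward recursions use per-step rescaling to avoid
underflow; Viterbi runs in log space.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["pack_sequences", "estep", "viterbi_paths", "forward_loglik"]


def pack_sequences(colors):
    """Concatenate per-burst color arrays; returns (flat int8, offsets int64)."""
    lens = np.array([len(c) for c in colors], dtype=np.int64)
    starts = np.zeros(len(colors) + 1, dtype=np.int64)
    np.cumsum(lens, out=starts[1:])
    flat = (
        np.concatenate([np.asarray(c, dtype=np.int8) for c in colors])
        if len(colors)
        else np.zeros(0, dtype=np.int8)
    )
    return flat, starts


@njit(cache=True)
def estep(obs, starts, pi, A, B):
    """One Baum-Welch expectation pass over all bursts.

    Returns (loglik, pi_num, xi_num, gamma_obs_num, burst_occ):
    pi_num[i]        — summed initial-photon posteriors,
    xi_num[i, j]     — expected i->j transition counts,
    gamma_obs_num[i, m] — expected photons emitted by state i as symbol m,
    burst_occ[b, i]  — expected photons in state i within burst b.
    """
    n = pi.shape[0]
    m = B.shape[1]
    nb = starts.shape[0] - 1
    pi_num = np.zeros(n)
    xi_num = np.zeros((n, n))
    gam_num = np.zeros((n, m))
    burst_occ = np.zeros((nb, n))
    loglik = 0.0
    max_T = 0
    for b in range(nb):
        if starts[b + 1] - starts[b] > max_T:
            max_T = starts[b + 1] - starts[b]
    alpha_buf = np.empty((max_T, n))
    c_buf = np.empty(max_T)
    beta = np.empty(n)
    beta_new = np.empty(n)
    for b in range(nb):
        i0, i1 = starts[b], starts[b + 1]
        T = i1 - i0
        if T == 0:
            continue
        alpha = alpha_buf
        c = c_buf
        # forward
        s = 0.0
        for i in range(n):
            alpha[0, i] = pi[i] * B[i, obs[i0]]
            s += alpha[0, i]
        c[0] = s
        for i in range(n):
            alpha[0, i] /= s
        for t in range(1, T):
            o = obs[i0 + t]
            s = 0.0
            for j in range(n):
                a = 0.0
                for i in range(n):
                    a += alpha[t - 1, i] * A[i, j]
                a *= B[j, o]
                alpha[t, j] = a
                s += a
            c[t] = s
            for j in range(n):
                alpha[t, j] /= s
            loglik += np.log(c[t])
        loglik += np.log(c[0])
        # backward + accumulation
        for i in range(n):
            beta[i] = 1.0
            g = alpha[T - 1, i]
            gam_num[i, obs[i1 - 1]] += g
            burst_occ[b, i] += g
        for t in range(T - 2, -1, -1):
            o1 = obs[i0 + t + 1]
            cinv = 1.0 / c[t + 1]
            for i in range(n):
                acc = 0.0
                ai = alpha[t, i] * cinv
                for j in range(n):
                    w = A[i, j] * B[j, o1] * beta[j]
                    xi_num[i, j] += ai * w
                    acc += w
                beta_new[i] = acc * cinv
            for i in range(n):
                beta[i] = beta_new[i]
            o = obs[i0 + t]
            for i in range(n):
                g = alpha[t, i] * beta[i]
                gam_num[i, o] += g
                burst_occ[b, i] += g
        for i in range(n):
            pi_num[i] += alpha[0, i] * beta[i]
    return loglik, pi_num, xi_num, gam_num, burst_occ


@njit(cache=True)
def forward_loglik(obs, starts, pi, A, B):
    """Total scaled-forward log-likelihood over all bursts."""
    n = pi.shape[0]
    nb = starts.shape[0] - 1
    loglik = 0.0
    prev = np.empty(n)
    cur = np.empty(n)
    for b in range(nb):
        i0, i1 = starts[b], starts[b + 1]
        if i1 == i0:
            continue
        s = 0.0
        for i in range(n):
            prev[i] = pi[i] * B[i, obs[i0]]
            s += prev[i]
        loglik += np.log(s)
        for i in range(n):
            prev[i] /= s
        for t in range(i0 + 1, i1):
            o = obs[t]
            s = 0.0
            for j in range(n):
                a = 0.0
                for i in range(n):
                    a += prev[i] * A[i, j]
                cur[j] = a * B[j, o]
                s += cur[j]
            loglik += np.log(s)
            for j in range(n):
                prev[j] = cur[j] / s
        # (cur reused next burst)
    return loglik


@njit(cache=True)
def viterbi_paths(obs, starts, log_pi, log_A, log_B):
    """Most-probable state path per burst (log-space max-product).

    Ties break toward the lower state index.  Returns (paths, logprobs) with
    paths flat-concatenated in the same layout as ``obs``.
    """
    n = log_pi.shape[0]
    nb = starts.shape[0] - 1
    paths = np.zeros(obs.shape[0], dtype=np.int64)
    logp = np.zeros(nb)
    for b in range(nb):
        i0, i1 = starts[b], starts[b + 1]
        T = i1 - i0
        if T == 0:
            logp[b] = 0.0
            continue
        delta = np.empty((T, n))
        psi = np.zeros((T, n), dtype=np.int64)
        for i in range(n):
            delta[0, i] = log_pi[i] + log_B[i, obs[i0]]
        for t in range(1, T):
            o = obs[i0 + t]
            for j in range(n):
                best = delta[t - 1, 0] + log_A[0, j]
                arg = 0
                for i in range(1, n):
                    v = delta[t - 1, i] + log_A[i, j]
                    if v > best:  # strict: ties keep the lower index
                        best = v
                        arg = i
                delta[t, j] = best + log_B[j, o]
                psi[t, j] = arg
        best = delta[T - 1, 0]
        arg = 0
        for i in range(1, n):
            if delta[T - 1, i] > best:
                best = delta[T - 1, i]
                arg = i
        logp[b] = best
        paths[i1 - 1] = arg
        for t in range(T - 1, 0, -1):
            arg = psi[t, arg]
            paths[i0 + t - 1] = arg
    return paths, logp
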