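"""Independent brute-force oracles for the test suite.

These deliberately avoid the recursions under test: likelihoods are computed
by exhaustive summation over every hidden-state path, the best path by
exhaustive arg-max, and burst detection by a literal scan over gaps.
"""

from __future__ import annotations

import numpy as np


def all_paths(n_states: int, length: int) -> np.ndarray:
    """All state paths as an array (n_states**length, length), lexicographic."""
    return np.indices((n_states,) * length).reshape(length, -1).T


def path_probabilities(pi, A, B, obs) -> np.ndarray:
    """Joint probability of (path, observations) for every hidden path."""
    obs = np.asarray(obs)
    paths = all_paths(len(pi), len(obs))
    p = pi[paths[:, 0]] * B[paths[:, 0], obs[0]]
    for t in range(1, len(obs)):
        p = p * A[paths[:, t - 1], paths[:, t]] * B[paths[:, t], obs[t]]
    return p


def enum_loglik(pi, A, B, obs) -> float:
    """log P(O | model) by exhaustive path summation."""
    return float(np.log(path_probabilities(pi, A, B, obs).sum()))


def enum_viterbi(pi, A, B, obs):
    """(best path, its joint probability) by exhaustive arg-max.

    Ties resolve to the lexicographically smallest path.
    """
    p = path_probabilities(pi, A, B, obs)
    i = int(np.argmax(p))
    return all_paths(len(pi), len(obs))[i], float(p[i])


def brute_force_bursts(times, cutoff, min_photons):
    """Burst index ranges [(start, stop), ...] by a literal scan over gaps."""
    out = []
    i = 0
    n = len(times)
    while i < n:
        j = i
        while j + 1 < n and times[j + 1] - times[j] < cutoff:
            j += 1
        if j - i + 1 >= min_photons:
            out.append((i, j + 1))
        i = j + 1
    return out


def random_model(rng, n_states: int):
    """Random valid HMM parameters without exact ties."""
    pi = rng.dirichlet(np.ones(n_states) * 2.0)
    A = rng.dirichlet(np.ones(n_states) * 2.0, size=n_states)
    e = rng.uniform(0.05, 0.95, size=n_states)
    B = np.column_stack([1 - e, e])
    return pi, A, B
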