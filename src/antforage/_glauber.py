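"""Numba kernels for Glauber (heat-bath) dynamics of the pairwise model.

One sweep = N single-site updates in random order; site i is set to +1 with
its conditional probability sigmoid(2 beta (h_i + sum_j J_ij s_j)).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _shuffled(order, n):
    for k in range(n - 1, 0, -1):
        j = np.random.randint(0, k + 1)
        order[k], order[j] = order[j], order[k]


@njit(cache=True)
def _sweep(h2, J2, state, order):
    n = state.shape[0]
    _shuffled(order, n)
    for k in range(n):
        i = order[k]
        f = h2[i]
        for j in range(n):
            f += J2[i, j] * state[j]
        p_plus = 1.0 / (1.0 + np.exp(-f))
        state[i] = 1 if np.random.random() < p_plus else -1


@njit(cache=True)
def sample_kernel(h, J, beta, n_samples, burn_in, thin, seed, init_state):
    """Equilibrium samples of spins (+-1), shape (n_samples, N)."""
    np.random.seed(seed)
    n = h.shape[0]
    h2 = 2.0 * beta * h
    J2 = 2.0 * beta * J
    state = init_state.copy()
    order = np.arange(n)
    out = np.empty((n_samples, n), dtype=np.int8)
    for _ in range(burn_in):
        _sweep(h2, J2, state, order)
    for s in range(n_samples):
        for _ in range(thin):
            _sweep(h2, J2, state, order)
        out[s] = state
    return out


@njit(cache=True)
def detection_kernel(h, J, beta, food_idx, max_sweeps, seed):
    """First sweep at which every food node has been occupied at least once,
    starting from the all-empty state; -1 when censored at max_sweeps."""
    np.random.seed(seed)
    n = h.shape[0]
    h2 = 2.0 * beta * h
    J2 = 2.0 * beta * J
    state = np.full(n, -1, dtype=np.int8)
    order = np.arange(n)
    seen = np.zeros(food_idx.shape[0], dtype=np.int8)
    n_seen = 0
    for sweep in range(1, max_sweeps + 1):
        _sweep(h2, J2, state, order)
        for k in range(food_idx.shape[0]):
            if seen[k] == 0 and state[food_idx[k]] == 1:
                seen[k] = 1
                n_seen += 1
        if n_seen == food_idx.shape[0]:
            return sweep
    return -1


@njit(cache=True)
def first_detection_kernel(h, J, beta, food_idx, max_sweeps, seed):
    """First sweep at which any one food node becomes occupied; -1 censored."""
    np.random.seed(seed)
    n = h.shape[0]
    h2 = 2.0 * beta * h
    J2 = 2.0 * beta * J
    state = np.full(n, -1, dtype=np.int8)
    order = np.arange(n)
    for sweep in range(1, max_sweeps + 1):
        _sweep(h2, J2, state, order)
        for k in range(food_idx.shape[0]):
            if state[food_idx[k]] == 1:
                return sweep
    return -1
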