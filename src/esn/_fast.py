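"""Compiled inner loop for large-scale first-level permutation runs.

The public per-unit API (``rate.shuffle_threshold`` / ``rate.group_test``)
is plain numpy; this kernel exists for calibration runs that repeat the
full 585-unit x 10^3-permutation first level hundreds of times.  It uses
an inline xorshift128+ generator (seeded via splitmix64) with
Lemire-style bounded sampling inside the Fisher-Yates shuffle; shuffle
uniformity and statistical agreement with the numpy path are covered by
tests.
"""

from __future__ import annotations

import numpy as np
from numba import int64, njit, uint64

_MASK = uint64(0xFFFFFFFFFFFFFFFF)


@njit(cache=True, inline="always")
def _splitmix64(state):
    state = (state + uint64(0x9E3779B97F4A7C15)) & _MASK
    z = state
    z = ((z ^ (z >> uint64(30))) * uint64(0xBF58476D1CE4E5B9)) & _MASK
    z = ((z ^ (z >> uint64(27))) * uint64(0x94D049BB133111EB)) & _MASK
    return state, z ^ (z >> uint64(31))


@njit(cache=True)
def first_level_kernel(z_enc, z_ret, n_perm, quantile, z_gate, seed):
    """Pooled-percentile thresholds and per-permutation ESN flags.

    For every unit (row): permute the encoding order ``n_perm`` times,
    pool all permuted products, take the linear-interpolation
    ``quantile``; a permutation flags the unit when any episode's
    permuted product reaches the threshold with both z-scores at the
    gate.  Returns (thresholds, perm_flags).
    """
    n_units, n_trials = z_enc.shape
    thresholds = np.empty(n_units)
    perm_flags = np.zeros((n_units, n_perm), dtype=np.bool_)

    s = uint64(seed)
    s, s0 = _splitmix64(s)
    s, s1 = _splitmix64(s)

    pooled = np.empty(n_perm * n_trials)
    gate_ok = np.empty((n_perm, n_trials), dtype=np.bool_)
    perm = np.empty(n_trials, dtype=np.int64)
    for u in range(n_units):
        for p in range(n_perm):
            for i in range(n_trials):
                perm[i] = i
            for i in range(n_trials - 1, 0, -1):
                x = s0
                y = s1
                s0 = y
                x ^= (x << uint64(23)) & _MASK
                s1 = x ^ y ^ (x >> uint64(17)) ^ (y >> uint64(26))
                r = (s1 + y) & _MASK
                j = int64(((r >> uint64(32)) * uint64(i + 1)) >> uint64(32))
                tmp = perm[i]
                perm[i] = perm[j]
                perm[j] = tmp
            for i in range(n_trials):
                e = z_enc[u, perm[i]]
                r_ = z_ret[u, i]
                pooled[p * n_trials + i] = e * r_
                gate_ok[p, i] = (e >= z_gate) and (r_ >= z_gate)
        thr = np.quantile(pooled, quantile)
        thresholds[u] = thr
        for p in range(n_perm):
            for i in range(n_trials):
                if gate_ok[p, i] and pooled[p * n_trials + i] >= thr:
                    perm_flags[u, p] = True
                    break
    return thresholds, perm_flags
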