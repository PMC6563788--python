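"""Compiled inner loops of the simulator and error detector.

Both kernels walk the grid once, carrying the accumulated reset as a
single exponentially decaying state variable: with r(k) the reset term at
step k, r(k+1) = (r(k) + theta * fired(k)) * exp(-dt/tau_m).  They are the
only per-step Python-level loops in a training run and are JIT-compiled.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["spike_scan", "first_error_scan"]


@njit(cache=True)
def spike_scan(v_free: np.ndarray, theta: float, d1: float) -> np.ndarray:
    """Grid indices where the reset-corrected potential reaches threshold.

    ``v_free`` is the reset-free weighted PSP superposition; ``d1`` is
    exp(-dt/tau_m).  At most one spike per step.
    """
    n = v_free.size
    spikes = np.empty(n, np.int64)
    cnt = 0
    r = 0.0
    for k in range(n):
        if v_free[k] - r >= theta:
            spikes[cnt] = k
            cnt += 1
            r = (r + theta) * d1
        else:
            r = r * d1
    return spikes[:cnt]


@njit(cache=True)
def first_error_scan(
    v_free: np.ndarray,
    theta: float,
    d1: float,
    lo: np.ndarray,
    hi: np.ndarray,
    d_idx: np.ndarray,
) -> tuple:
    """Simulate and stop at the first wrong spike time.

    Windows are index intervals [lo[j], hi[j]] around the desired indices
    ``d_idx``, matched in chronological order.  Returns (kind, index,
    n_matched) with kind 0 = stray spike (a), 1 = duplicate in a matched
    window (b), 2 = missed window (c, index is the desired index), and
    -1 = no error.  A window closing unmatched is checked before any spike
    at the same step is classified, so a missed window takes precedence.
    The potential past the error is never evaluated.
    """
    n = v_free.size
    m = d_idx.size
    j = 0
    r = 0.0
    for k in range(n):
        if j < m and k > hi[j]:
            return 2, d_idx[j], j
        if v_free[k] - r >= theta:
            if j < m and lo[j] <= k <= hi[j]:
                j += 1
            elif j > 0 and k <= hi[j - 1]:
                return 1, k, j
            else:
                return 0, k, j
            r = (r + theta) * d1
        else:
            r = r * d1
    if j < m:
        return 2, d_idx[j], j
    return -1, 0, j
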