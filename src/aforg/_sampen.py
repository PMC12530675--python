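"""Exact template-match pair counting for sample entropy.

Counts, over all ordered template pairs i < j, how many length-``m``
templates match within a Chebyshev tolerance ``r`` (count B) and how many
of those still match when extended to length ``m + 1`` (count A).
Self-matches are excluded by construction. Both templates are taken from
the first ``N - m`` positions so A and B are counted over the same
template set (the standard convention).

The m = 2 fast path is a branch-free numba kernel: electrogram segments
have a dense baseline cluster where almost every first-coordinate pair
matches, which defeats early-exit and tree pruning strategies, whereas a
straight-line counted loop vectorizes well.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _counts_m2(x: np.ndarray, r: float):
    n_tpl = x.shape[0] - 2
    A = 0
    B = 0
    for i in range(n_tpl - 1):
        xi0 = x[i]
        xi1 = x[i + 1]
        xi2 = x[i + 2]
        b = 0
        a = 0
        for j in range(i + 1, n_tpl):
            c0 = abs(xi0 - x[j]) <= r
            c1 = abs(xi1 - x[j + 1]) <= r
            c2 = abs(xi2 - x[j + 2]) <= r
            cb = c0 and c1
            b += 1 if cb else 0
            a += 1 if (cb and c2) else 0
        B += b
        A += a
    return A, B


@njit(cache=True)
def _counts_generic(x: np.ndarray, m: int, r: float):
    n_tpl = x.shape[0] - m
    A = 0
    B = 0
    for i in range(n_tpl - 1):
        for j in range(i + 1, n_tpl):
            ok = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    ok = False
                    break
            if ok:
                B += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    A += 1
    return A, B


def sampen_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Return ``(A, B)`` template-match counts for a 1-D series."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    if m == 2:
        return _counts_m2(x, float(r))
    return _counts_generic(x, int(m), float(r))
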