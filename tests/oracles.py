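"""Independent reference implementations used only to cross-check the
package's computations. Deliberately written with different constructions
from the library code paths (row-wise template comparison instead of a
compiled pair counter; explicit bin arithmetic instead of np.histogram;
textbook statistic formulas instead of scipy calls)."""

from __future__ import annotations

import math

import numpy as np


def sampen_bruteforce(x: np.ndarray, m: int, r: float) -> float:
    """Sample entropy by exhaustive template-pair enumeration."""
    x = np.asarray(x, dtype=float)
    n_tpl = len(x) - m
    Xm = np.array([x[i : i + m] for i in range(n_tpl)])
    tail = x[m : m + n_tpl]
    A = B = 0
    for i in range(n_tpl - 1):
        d = np.max(np.abs(Xm[i + 1 :] - Xm[i]), axis=1) <= r
        B += int(d.sum())
        A += int((d & (np.abs(tail[i + 1 :] - tail[i]) <= r)).sum())
    if A == 0 or B == 0:
        return float("nan")
    return -math.log(A / B)


def shen_bruteforce(x: np.ndarray, n_bins: int) -> float:
    """Shannon entropy of equal-width amplitude bins, by explicit
    per-sample bin arithmetic."""
    x = np.asarray(x, dtype=float)
    lo, hi = min(x), max(x)
    if hi == lo:
        return 0.0
    width = (hi - lo) / n_bins
    counts = [0] * n_bins
    for v in x:
        k = int((v - lo) / width)
        if k == n_bins:  # the maximum lands in the last bin
            k = n_bins - 1
        counts[k] += 1
    total = len(x)
    return -sum((c / total) * math.log2(c / total) for c in counts if c)


def dagostino_k2(x: np.ndarray) -> tuple[float, float]:
    """D'Agostino-Pearson omnibus K^2 from the published z-transforms of
    sample skewness and kurtosis; p from the chi-square(2) tail."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    mu = x.mean()
    m2 = ((x - mu) ** 2).mean()
    m3 = ((x - mu) ** 3).mean()
    m4 = ((x - mu) ** 4).mean()
    g1 = m3 / m2**1.5
    b2 = m4 / m2**2

    # skewness z (D'Agostino 1970)
    y = g1 * math.sqrt((n + 1) * (n + 3) / (6.0 * (n - 2)))
    bv = 3.0 * (n**2 + 27 * n - 70) * (n + 1) * (n + 3) / (
        (n - 2.0) * (n + 5) * (n + 7) * (n + 9)
    )
    w2 = -1 + math.sqrt(2 * (bv - 1))
    delta = 1 / math.sqrt(0.5 * math.log(w2))
    alpha = math.sqrt(2.0 / (w2 - 1))
    y = max(y, 1e-300) if y == 0 else y
    z1 = delta * math.log(y / alpha + math.sqrt((y / alpha) ** 2 + 1))

    # kurtosis z (Anscombe & Glynn 1983)
    e = 3.0 * (n - 1) / (n + 1)
    var = 24.0 * n * (n - 2) * (n - 3) / ((n + 1) ** 2 * (n + 3) * (n + 5))
    xx = (b2 - e) / math.sqrt(var)
    beta = 6.0 * (n**2 - 5 * n + 2) / ((n + 7) * (n + 9)) * math.sqrt(
        6.0 * (n + 3) * (n + 5) / (n * (n - 2) * (n - 3))
    )
    a = 6.0 + 8.0 / beta * (2.0 / beta + math.sqrt(1 + 4.0 / beta**2))
    term = (1 - 2.0 / a) / (1 + xx * math.sqrt(2.0 / (a - 4)))
    z2 = (
        (1 - 2.0 / (9 * a)) - math.copysign(abs(term) ** (1.0 / 3), term)
    ) / math.sqrt(2.0 / (9 * a))

    k2 = z1**2 + z2**2
    # chi-square(2) survival function has the closed form exp(-k2/2)
    return k2, math.exp(-k2 / 2.0)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float) - np.mean(x)
    y = np.asarray(y, float) - np.mean(y)
    return float((x * y).sum() / math.sqrt((x**2).sum() * (y**2).sum()))


def _ranks(v: np.ndarray) -> np.ndarray:
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(len(v))
    ranks[order] = np.arange(1, len(v) + 1, dtype=float)
    # average ties
    for val in np.unique(v):
        mask = v == val
        if mask.sum() > 1:
            ranks[mask] = ranks[mask].mean()
    return ranks


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    return pearson_r(_ranks(np.asarray(x, float)), _ranks(np.asarray(y, float)))


def paired_t(pre: np.ndarray, post: np.ndarray) -> tuple[float, float]:
    """Paired t statistic and two-sided p via the t survival function."""
    from scipy.special import stdtr

    d = np.asarray(pre, float) - np.asarray(post, float)
    n = len(d)
    t = d.mean() / (d.std(ddof=1) / math.sqrt(n))
    p = 2.0 * (1.0 - stdtr(n - 1, abs(t)))
    return t, p
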