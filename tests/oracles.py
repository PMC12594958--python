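"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by direct enumeration or direct
definition, sharing no code path with the implementation it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def bh_reject(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg by the textbook sorted-p definition."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresh = alpha * (np.arange(1, m + 1)) / m
    below = np.nonzero(sorted_p <= thresh)[0]
    reject = np.zeros(m, dtype=bool)
    if below.size:
        reject[order[: below[-1] + 1]] = True
    return reject


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exact-rational hypergeometric enumeration."""
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1, c1 = a + b, a + c
    denom = comb(n, c1)
    pmf = {
        k: Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom)
        for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
    }
    p_obs = pmf[a]
    tol = p_obs + p_obs / 10**9
    total = sum(p for p in pmf.values() if p <= tol)
    return float(min(Fraction(1), total))


def dtw_cost_bruteforce(a: np.ndarray, b: np.ndarray) -> float:
    """Exponential-time recursive DTW cost (for tiny sequences only)."""
    from functools import lru_cache

    a = np.asarray(a, float)
    b = np.asarray(b, float)

    def dist(i, j):
        return float(np.hypot(*(a[i] - b[j])))

    @lru_cache(maxsize=None)
    def rec(i, j):
        if i == 0 and j == 0:
            return dist(0, 0)
        best = np.inf
        if i > 0:
            best = min(best, rec(i - 1, j))
        if j > 0:
            best = min(best, rec(i, j - 1))
        if i > 0 and j > 0:
            best = min(best, rec(i - 1, j - 1))
        return best + dist(i, j)

    return rec(len(a) - 1, len(b) - 1)


def circle_crossings(segments, centre, radius: float) -> int:
    """Number of times a polyline forest crosses a circle.

    Counts sign changes of (distance - radius) along each segment, which for
    radially monotone trees equals the number of branches alive at that
    radius.
    """
    k = 0
    for r0, c0, r1, c1 in segments:
        d0 = np.hypot(r0 - centre[0], c0 - centre[1])
        d1 = np.hypot(r1 - centre[0], c1 - centre[1])
        if (d0 - radius) * (d1 - radius) < 0:
            k += 1
    return k


def b3_smooth_direct(image: np.ndarray) -> np.ndarray:
    """Direct 2-D convolution with the separable B3 kernel, mirror boundary."""
    k1 = np.array([1, 4, 6, 4, 1]) / 16.0
    kernel = np.outer(k1, k1)
    h, w = image.shape
    padded = np.pad(image, 2, mode="reflect")
    out = np.zeros_like(image, dtype=float)
    for i in range(h):
        for j in range(w):
            out[i, j] = (padded[i : i + 5, j : j + 5] * kernel).sum()
    return out
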