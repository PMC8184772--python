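"""Exact null distribution of Spearman's S = sum((rank_x - rank_y)^2).

For tie-free data the permutation null of S is computed exactly: counts
of T = sum(i * pi(i)) over all n! permutations are accumulated by a
bitmask dynamic program (counts up to 16! are integers below 2^53, so
float64 arithmetic is exact), and S = n(n+1)(2n+1)/3 - 2T. Distributions
for n = 4..16 are shipped as a precomputed probability table
(data/spearman_s_null.json, generated by the same DP and verified
against full permutation enumeration for n <= 8); other small n are
computed on demand. Exact tails matter for the Bonferroni-thresholded
correlation network, where the t approximation is too liberal in the
far tail and inflates the family-wise edge error.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import numpy as np

_DP_MAX_N = 13  # on-demand DP beyond the table stays below ~100 MB


def s_max(n: int) -> int:
    return n * (n * n - 1) // 3


def _dist_T(n: int) -> np.ndarray:
    L = sum(i * i for i in range(1, n + 1)) + 1
    f = np.zeros((1 << n, L))
    f[0, 0] = 1.0
    pop = np.array([bin(m).count("1") for m in range(1 << n)])
    for m in np.argsort(pop, kind="stable"):
        pm = pop[m]
        if pm == n:
            continue
        fm = f[m]
        if not fm.any():
            continue
        row = pm + 1
        for j in range(1, n + 1):
            bit = 1 << (j - 1)
            if m & bit:
                continue
            shift = row * j
            f[m | bit, shift:] += fm[: L - shift]
    return f[(1 << n) - 1]


def _pmf_by_dp(n: int) -> np.ndarray:
    counts = _dist_T(n)
    c = n * (n + 1) * (2 * n + 1) // 3
    pmf = np.zeros(s_max(n) // 2 + 1)
    for T, k in enumerate(counts):
        if k > 0:
            pmf[(c - 2 * T) // 2] += k
    return pmf / pmf.sum()


@lru_cache(maxsize=None)
def _table() -> dict[int, np.ndarray]:
    path = resources.files("cytogravity").joinpath("data/spearman_s_null.json")
    with path.open("r", encoding="utf-8") as fh:
        raw = json.load(fh)
    return {int(k): np.asarray(v) for k, v in raw.items()}


@lru_cache(maxsize=32)
def s_null_pmf(n: int) -> np.ndarray | None:
    """P(S = 2k) for k = 0..s_max(n)/2, or None when n is out of reach.

    S is always even because sum(rank differences) = 0 fixes its parity.
    """
    if n < 2:
        return None
    tab = _table()
    if n in tab:
        return tab[n]
    if n <= _DP_MAX_N:
        return _pmf_by_dp(n)
    return None


def exact_two_sided_p(n: int, s: float) -> float | None:
    """Exact two-sided p-value 2 * min(P(S <= s), P(S >= s)), capped at 1.

    Returns None when no exact distribution is available for ``n``
    (caller falls back to an approximation). ``s`` may be fractional
    only through floating arithmetic on tie-free ranks; it is rounded
    to the nearest attainable even value.
    """
    pmf = s_null_pmf(n)
    if pmf is None:
        return None
    k = int(round(s / 2.0))
    k = min(max(k, 0), pmf.size - 1)
    cdf = np.cumsum(pmf)
    p_le = float(cdf[k])
    p_ge = float(1.0 - (cdf[k - 1] if k > 0 else 0.0))
    return min(1.0, 2.0 * min(p_le, p_ge))
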