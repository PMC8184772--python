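"""Small-sample nonparametric statistics for the paired study design.

Contains the exact Wilcoxon signed-rank test (complete sign-assignment
distribution up to n = 25), the two-stage adaptive linear step-up FDR
procedure of Benjamini, Krieger and Yekutieli, Spearman correlation with
exact permutation p-values at very small n, and the 2^-ddCt qPCR
relative-quantification utility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

EXACT_WILCOXON_MAX_N = 25
EXACT_SPEARMAN_MAX_N = 8


class UndefinedTestError(ValueError):
    """The requested test is undefined for the given input (e.g. all-zero
    differences)."""


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float  # W+ = sum of ranks of positive differences
    p_two_sided: float
    n_effective: int  # pairs remaining after zero removal
    method: str  # "exact" or "normal"


def _signed_rank_distribution(double_ranks: np.ndarray) -> np.ndarray:
    """Exact distribution of 2*W+ over all 2^n sign assignments.

    Midranks are doubled so every rank contribution is an integer; the
    convolution product of (1 + z^r_i) enumerates the full distribution
    without explicitly visiting the 2^n assignments.
    """
    total = int(double_ranks.sum())
    poly = np.zeros(total + 1)
    poly[0] = 1.0
    for r in double_ranks:
        r = int(r)
        shifted = np.zeros_like(poly)
        shifted[r:] = poly[: poly.size - r]
        poly = poly + shifted
    return poly / poly.sum()


def wilcoxon_signed_rank_exact(differences) -> PairedTestResult:
    """Exact two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; tied magnitudes receive midranks. For
    n <= 25 remaining pairs the p-value comes from the complete
    sign-assignment distribution (ties handled exactly); above that a
    normal approximation with tie correction and continuity correction
    is used.
    """
    d = np.asarray(differences, dtype=float)
    if not np.isfinite(d).all():
        raise ValueError("differences must be finite")
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise UndefinedTestError("all differences are zero; signed-rank test undefined")

    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())

    if n <= EXACT_WILCOXON_MAX_N:
        double_ranks = np.rint(2 * ranks).astype(int)
        dist = _signed_rank_distribution(double_ranks)
        w2 = int(round(2 * w_pos))
        cdf = np.cumsum(dist)
        p_le = float(cdf[w2])
        p_ge = float(1.0 - (cdf[w2 - 1] if w2 > 0 else 0.0))
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return PairedTestResult(w_pos, p, n, "exact")

    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    z = (w_pos - mean - 0.5 * np.sign(w_pos - mean)) / np.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return PairedTestResult(w_pos, p, n, "normal")


@dataclass
class FDRResult:
    q_level: float
    p_values: np.ndarray
    discoveries: np.ndarray  # boolean flags, original order
    m0: int  # estimated number of true nulls
    stage1_rejections: int

    @property
    def n_discoveries(self) -> int:
        return int(self.discoveries.sum())


def _linear_step_up(p: np.ndarray, level: float) -> np.ndarray:
    """Benjamini-Hochberg linear step-up; returns boolean rejection flags."""
    m = p.size
    order = np.argsort(p, kind="stable")
    thresholds = level * (np.arange(1, m + 1) / m)
    passed = p[order] <= thresholds
    flags = np.zeros(m, dtype=bool)
    if passed.any():
        k = int(np.max(np.flatnonzero(passed)))
        flags[order[: k + 1]] = True
    return flags


def bky_two_stage_fdr(p_values, q: float) -> FDRResult:
    """Two-stage adaptive linear step-up FDR control.

    Stage 1 runs the linear step-up at q' = q/(1+q); with r1 rejections,
    m0 = m - r1 estimates the true nulls, and stage 2 re-runs the step-up
    at level q * m / m0. Stage-1 outcomes of 0 or m rejections are final.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError(f"q must be in (0, 1), got {q}")

    m = p.size
    q_prime = q / (1.0 + q)
    stage1 = _linear_step_up(p, q_prime)
    r1 = int(stage1.sum())
    if r1 == 0 or r1 == m:
        return FDRResult(q, p, stage1, m0=m - r1, stage1_rejections=r1)
    m0 = m - r1
    stage2 = _linear_step_up(p, q * m / m0)
    return FDRResult(q, p, stage2, m0=m0, stage1_rejections=r1)


def spearman_rho_p(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Midranks handle ties. For n <= 8 the p-value is the exact tail
    probability over all n! rank permutations; above that the standard
    t-approximation is used. Constant inputs yield (nan, nan), flagging
    an undefined correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n <= EXACT_SPEARMAN_MAX_N:
        from itertools import permutations

        perms = np.array(list(permutations(ry)))
        rx_c = rx - rx.mean()
        perms_c = perms - perms.mean(axis=1, keepdims=True)
        num = perms_c @ rx_c
        denom = np.sqrt((rx_c**2).sum() * (perms_c**2).sum(axis=1))
        rho_perm = num / denom
        p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
        return rho, p

    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = float(min(1.0, 2.0 * sps.t.sf(abs(t), df=n - 2)))
    return rho, p


@dataclass(frozen=True)
class QPCRRecord:
    """Ct values for one target/reference gene pair under two conditions."""

    ct_target_control: float
    ct_reference_control: float
    ct_target_treated: float
    ct_reference_treated: float

    def __post_init__(self) -> None:
        for v in (
            self.ct_target_control,
            self.ct_reference_control,
            self.ct_target_treated,
            self.ct_reference_treated,
        ):
            if v is None or not np.isfinite(v) or v <= 0:
                raise ValueError("all Ct values must be positive finite reals")


def ddct_fold_change(record: QPCRRecord) -> float:
    """Relative expression by the 2^-ddCt method (reference-normalized)."""
    dct_control = record.ct_target_control - record.ct_reference_control
    dct_treated = record.ct_target_treated - record.ct_reference_treated
    ddct = dct_treated - dct_control
    return float(2.0 ** (-ddct))
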