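"""Elastic-net stratification of gravity conditions, fitted from scratch.

The model minimizes the penalized squared-error objective

    L(beta) = |Y - X beta|^2 + lambda1 |beta|_1 + lambda2 |beta|_2^2

by cyclic coordinate descent with exact soft-threshold updates, on
internally standardized features and a centered outcome (Y encodes the
gravity condition as sµG = +1, 1G = -1; the squared-error loss is used
for the binary outcome exactly as written, not a logistic surrogate).
Penalties are parametrized as lambda1 = alpha * lambda and
lambda2 = (1 - alpha) * lambda with mixing fraction alpha.

Cross-validation is leave-one-donor-out: both of a donor's rows (1G and
sµG) are held out together so that donor-level correlation never leaks
into the training fold, and features are re-standardized within each
training fold. The per-lambda error is the paired misclassification rate
from the sign of pair-centered out-of-fold scores. Both the minimum-error
penalty (lambda_min, largest lambda attaining the minimum) and the
one-standard-error penalty (lambda_1se) are reported; model significance
feeds the per-donor out-of-fold score differences to the exact Wilcoxon
signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import PairedTestResult, UndefinedTestError, wilcoxon_signed_rank_exact


class DataError(ValueError):
    pass


def en_objective(X, Y, beta, lambda1: float, lambda2: float, intercept: float = 0.0,
                 squared_l2: bool = True) -> float:
    """Evaluate the elastic-net objective exactly as defined.

    By default the ridge term is the squared norm lambda2 * |beta|_2^2
    (the form under which coordinate-wise soft-threshold updates are
    exact); ``squared_l2=False`` evaluates the literal unsquared-norm
    variant for reporting purposes only.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if X.shape[0] != Y.shape[0] or X.shape[1] != beta.shape[0]:
        raise ValueError("shape mismatch between X, Y and beta")
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("penalties must be nonnegative")
    resid = Y - intercept - X @ beta
    l2 = float(beta @ beta) if squared_l2 else float(np.sqrt(beta @ beta))
    return float(resid @ resid + lambda1 * np.abs(beta).sum() + lambda2 * l2)


def _soft_threshold(z: float, gamma: float) -> float:
    if z > gamma:
        return z - gamma
    if z < -gamma:
        return z + gamma
    return 0.0


def _cd_sweeps_py(G, c, lambda1, lambda2, beta, tol, max_sweeps):
    p = c.size
    grad = c - G @ beta
    diag = np.diag(G).copy()
    max_delta = np.inf
    sweeps = 0
    while sweeps < max_sweeps and max_delta >= tol:
        max_delta = 0.0
        for j in range(p):
            dj = diag[j]
            denom = dj + lambda2
            if denom <= 0:
                continue  # constant column: coefficient stays 0
            bj = beta[j]
            rho = grad[j] + dj * bj
            new = _soft_threshold(rho, lambda1 / 2.0) / denom
            delta = new - bj
            if delta != 0.0:
                beta[j] = new
                grad -= G[j] * delta  # G symmetric: row j == column j
                if abs(delta) > max_delta:
                    max_delta = abs(delta)
        sweeps += 1
    return sweeps, max_delta


try:  # optional JIT of the hot loop; the pure-numpy path is the reference
    import numba as _numba

    @_numba.njit(cache=True)
    def _cd_sweeps_jit(G, c, lambda1, lambda2, beta, tol, max_sweeps):  # pragma: no cover
        p = c.size
        grad = c - G @ beta
        half_l1 = lambda1 / 2.0
        max_delta = 1e300
        sweeps = 0
        while sweeps < max_sweeps and max_delta >= tol:
            max_delta = 0.0
            for j in range(p):
                dj = G[j, j]
                denom = dj + lambda2
                if denom <= 0:
                    continue
                bj = beta[j]
                rho = grad[j] + dj * bj
                if rho > half_l1:
                    new = (rho - half_l1) / denom
                elif rho < -half_l1:
                    new = (rho + half_l1) / denom
                else:
                    new = 0.0
                delta = new - bj
                if delta != 0.0:
                    beta[j] = new
                    for k in range(p):
                        grad[k] -= G[j, k] * delta
                    if abs(delta) > max_delta:
                        max_delta = abs(delta)
            sweeps += 1
        return sweeps, max_delta

    _cd_sweeps = _cd_sweeps_jit
except Exception:  # noqa: BLE001
    _cd_sweeps = _cd_sweeps_py


def _cd_solve(G, c, lambda1, lambda2, beta, tol, max_sweeps):
    """Cyclic coordinate descent on the Gram formulation.

    grad tracks c - G @ beta; the per-coordinate minimizer is
    soft(rho_j, lambda1/2) / (G_jj + lambda2) with
    rho_j = grad_j + G_jj * beta_j. Returns (beta, n_sweeps, max_delta).
    """
    G = np.ascontiguousarray(G, dtype=np.float64)
    c = np.ascontiguousarray(c, dtype=np.float64)
    beta = np.ascontiguousarray(beta, dtype=np.float64)
    sweeps, max_delta = _cd_sweeps(G, c, float(lambda1), float(lambda2), beta, float(tol), int(max_sweeps))
    return beta, sweeps, max_delta


@dataclass
class ENFit:
    """A fitted elastic net (coefficients on the standardized scale)."""

    beta: np.ndarray
    intercept: float
    lambda1: float
    lambda2: float
    objective: float
    n_sweeps: int
    converged: bool
    kkt_residual: float  # stationarity residual in coefficient units
    col_mean: np.ndarray
    col_scale: np.ndarray

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.beta))

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Xs = (X - self.col_mean) / self.col_scale
        return Xs @ self.beta + self.intercept


def _standardize(X):
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale_safe = np.where(scale > 0, scale, 1.0)
    return (X - mean) / scale_safe, mean, scale_safe, scale == 0


def fit_en(X, Y, lambda1: float, lambda2: float, tol: float = 1e-8,
           max_sweeps: int = 2000, beta0: np.ndarray | None = None) -> ENFit:
    """Fit the elastic net by cyclic coordinate descent.

    Features are standardized and Y centered internally. Constant columns
    keep a zero coefficient. The fit is flagged unconverged (never
    silently accepted) if the sweep budget is exhausted; ``beta0`` allows
    warm starts along a penalty path.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise DataError("X and Y must be finite")
    if X.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise DataError("X must be 2-D with one row per element of Y")
    if X.shape[0] < 2:
        raise DataError("need at least 2 samples")
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("penalties must be nonnegative")

    Xs, mean, scale, constant = _standardize(X)
    Xs = np.ascontiguousarray(Xs)
    ybar = float(Y.mean())
    yc = Y - ybar

    G = Xs.T @ Xs
    if constant.any():
        # zero the Gram diagonal so _cd_solve skips these coordinates
        idx = np.flatnonzero(constant)
        G[idx, :] = 0.0
        G[:, idx] = 0.0
    c = Xs.T @ yc

    beta = np.zeros(Xs.shape[1]) if beta0 is None else np.array(beta0, dtype=float)
    beta, sweeps, max_delta = _cd_solve(G, c, lambda1, lambda2, beta, tol, max_sweeps)
    converged = max_delta < tol
    obj = en_objective(Xs, yc, beta, lambda1, lambda2)
    return ENFit(
        beta=beta,
        intercept=ybar,
        lambda1=lambda1,
        lambda2=lambda2,
        objective=obj,
        n_sweeps=sweeps,
        converged=converged,
        kkt_residual=float(max_delta),
        col_mean=mean,
        col_scale=scale,
    )


def lambda_max(X, Y, mixing: float = 0.5) -> float:
    """Smallest overall penalty that fully shrinks beta to zero
    (on standardized features): lambda1 >= 2 max_j |x_j^T (Y - Ybar)|."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    Xs, _, _, _ = _standardize(X)
    l1_max = 2.0 * float(np.max(np.abs(Xs.T @ (Y - Y.mean()))))
    if mixing <= 0:
        raise ValueError("mixing must be positive to derive a finite lambda_max")
    return l1_max / mixing


@dataclass
class CVResult:
    lambda_grid: np.ndarray  # descending
    cv_error_mean: np.ndarray
    cv_error_sd: np.ndarray
    lambda_min: float
    lambda_1se: float
    idx_min: int
    idx_1se: int
    mixing: float
    fold_donors: list[str]
    oof_scores: pd.DataFrame  # rows (donor, gravity-sign), one column per lambda index
    donors: np.ndarray
    y: np.ndarray
    fit_min: ENFit
    fit_1se: ENFit
    degenerate: bool = False
    notes: list[str] = field(default_factory=list)

    def fit(self, which: str = "1se") -> ENFit:
        return self.fit_1se if which == "1se" else self.fit_min


class PairingError(ValueError):
    pass


def _check_pairs(donors: np.ndarray, y: np.ndarray) -> list:
    uniq = sorted(set(donors.tolist()))
    constant = bool(np.ptp(y) == 0)
    for d in uniq:
        ys = np.sort(y[donors == d])
        if ys.size != 2:
            raise PairingError(f"donor {d!r} must contribute exactly two rows")
        if not constant and not (ys[0] == -1 and ys[1] == 1):
            raise PairingError(f"donor {d!r} must contribute exactly one +1 and one -1 row")
    return uniq


def cv_lambda_path(
    X,
    Y,
    donors,
    lambda_grid=None,
    mixing: float = 0.5,
    n_lambda: int = 50,
    decades: float = 4.0,
    tol: float = 1e-8,
    max_sweeps: int = 2000,
    seed: int = 0,
) -> CVResult:
    """Leave-one-donor-out cross-validation over a penalty path.

    Folds hold out both of a donor's rows together; features are
    standardized within each training fold only. The per-lambda error is
    the paired sign error of pair-centered out-of-fold scores (exact ties
    count 1/2). ``seed`` is accepted for interface stability; the fold
    structure is fully determined by the donors, so no randomness is
    consumed.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    donors = np.asarray(donors)
    uniq = _check_pairs(donors, Y)
    if len(uniq) < 3:
        raise PairingError("need at least 3 donors for cross-validation")

    degenerate = bool(np.ptp(Y) == 0)
    notes: list[str] = []
    if lambda_grid is None:
        lmax = lambda_max(X, Y, mixing)
        if lmax == 0:
            degenerate = True
            lmax = 1.0
            notes.append("lambda_max degenerate (Y uncorrelated with every feature)")
        lambda_grid = np.logspace(np.log10(lmax), np.log10(lmax) - decades, n_lambda)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if np.any(np.diff(lambda_grid) > 0):
        lambda_grid = np.sort(lambda_grid)[::-1]

    n_l, n_folds = lambda_grid.size, len(uniq)
    errors = np.zeros((n_l, n_folds))
    scores = np.zeros((n_l, X.shape[0]))

    y_constant = bool(np.ptp(Y) == 0)
    for f, donor in enumerate(uniq):
        test = donors == donor
        train = ~test
        beta = None
        if not y_constant:
            i_pos = np.flatnonzero(test & (Y > 0))[0]
            i_neg = np.flatnonzero(test & (Y < 0))[0]
        for li, lam in enumerate(lambda_grid):
            fit = fit_en(
                X[train], Y[train], mixing * lam, (1 - mixing) * lam,
                tol=tol, max_sweeps=max_sweeps, beta0=beta,
            )
            beta = fit.beta.copy()
            s = fit.predict(X[test])
            scores[li, test] = s
            if y_constant:
                errors[li, f] = 0.5  # no contrast to classify
                continue
            s_pos, s_neg = float(fit.predict(X[[i_pos]])[0]), float(fit.predict(X[[i_neg]])[0])
            if s_pos > s_neg:
                errors[li, f] = 0.0
            elif s_pos < s_neg:
                errors[li, f] = 1.0
            else:
                errors[li, f] = 0.5

    mean = errors.mean(axis=1)
    sd = errors.std(axis=1, ddof=1)
    idx_min = int(np.argmin(mean))  # grid is descending: first = largest lambda
    se = sd[idx_min] / np.sqrt(n_folds)
    within = np.flatnonzero(mean <= mean[idx_min] + se)
    idx_1se = int(within[0])  # largest lambda within one SE
    if np.ptp(mean) == 0:
        degenerate = True
        notes.append("flat cross-validation error curve; lambda selection degenerate")

    fits = {}
    for idx in {idx_min, idx_1se}:
        lam = lambda_grid[idx]
        fits[idx] = fit_en(X, Y, mixing * lam, (1 - mixing) * lam, tol=tol, max_sweeps=max_sweeps)

    oof = pd.DataFrame(
        scores.T,
        index=pd.MultiIndex.from_arrays([donors, Y], names=["donor", "y"]),
        columns=[f"lambda_{i}" for i in range(n_l)],
    )
    return CVResult(
        lambda_grid=lambda_grid,
        cv_error_mean=mean,
        cv_error_sd=sd,
        lambda_min=float(lambda_grid[idx_min]),
        lambda_1se=float(lambda_grid[idx_1se]),
        idx_min=idx_min,
        idx_1se=idx_1se,
        mixing=mixing,
        fold_donors=[str(d) for d in uniq],
        oof_scores=oof,
        donors=donors,
        y=Y,
        fit_min=fits[idx_min],
        fit_1se=fits[idx_1se],
        degenerate=degenerate,
        notes=notes,
    )


@dataclass
class ModelSignificance:
    donor_ids: list[str]
    score_pairs: list[tuple[float, float]]  # (sµG score, 1G score) per donor
    differences: np.ndarray
    test: PairedTestResult
    which_lambda: str


def model_significance(cv: CVResult, which: str = "1se") -> ModelSignificance:
    """Paired significance of the cross-validated model.

    Per donor, the out-of-fold score difference (sµG - 1G) at the chosen
    penalty is tested with the exact Wilcoxon signed-rank test. All-zero
    differences (a fully shrunk model) raise
    :class:`~cytogravity.stats.UndefinedTestError`.

    .. note::
       The penalty here is the one selected on the *same* error curve
       these scores produced, so the resulting p-value is optimistically
       biased under the null. :func:`nested_model_significance` removes
       that selection bias and is what the pipeline reports.
    """
    if np.ptp(cv.y) == 0:
        raise UndefinedTestError("constant outcome: no paired contrast to test")
    idx = cv.idx_1se if which == "1se" else cv.idx_min
    col = f"lambda_{idx}"
    donors, pairs, diffs = [], [], []
    donor_strs = cv.donors.astype(str)
    for d in cv.fold_donors:
        sel = donor_strs == d
        s_pos = float(cv.oof_scores[col].to_numpy()[sel & (cv.y > 0)][0])
        s_neg = float(cv.oof_scores[col].to_numpy()[sel & (cv.y < 0)][0])
        donors.append(d)
        pairs.append((s_pos, s_neg))
        diffs.append(s_pos - s_neg)
    diffs = np.array(diffs)
    test = wilcoxon_signed_rank_exact(diffs)
    return ModelSignificance(donors, pairs, diffs, test, which)


def nested_model_significance(
    X,
    Y,
    donors,
    which: str = "1se",
    mixing: float = 0.5,
    n_lambda: int = 50,
    decades: float = 4.0,
    tol: float = 1e-8,
    max_sweeps: int = 2000,
    seed: int = 0,
) -> ModelSignificance:
    """Selection-bias-free paired significance via nested cross-validation.

    For each held-out donor the penalty is chosen by an inner
    leave-one-donor-out CV on the remaining donors only; the donor's two
    rows are then scored by a model refit on those donors at the inner
    penalty. The held-out scores are therefore independent of every
    selection decision, so under the null the per-donor score differences
    are sign-symmetric and the exact Wilcoxon signed-rank p-value is
    calibrated.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    donors = np.asarray(donors)
    if np.ptp(Y) == 0:
        raise UndefinedTestError("constant outcome: no paired contrast to test")
    uniq = _check_pairs(donors, Y)
    if len(uniq) < 4:
        raise PairingError("nested CV needs at least 4 donors")

    donor_ids, pairs, diffs = [], [], []
    for d in uniq:
        test = donors == d
        train = ~test
        inner = cv_lambda_path(
            X[train], Y[train], donors[train],
            mixing=mixing, n_lambda=n_lambda, decades=decades,
            tol=tol, max_sweeps=max_sweeps, seed=seed,
        )
        fit = inner.fit(which)
        i_pos = np.flatnonzero(test & (Y > 0))[0]
        i_neg = np.flatnonzero(test & (Y < 0))[0]
        s_pos = float(fit.predict(X[[i_pos]])[0])
        s_neg = float(fit.predict(X[[i_neg]])[0])
        donor_ids.append(str(d))
        pairs.append((s_pos, s_neg))
        diffs.append(s_pos - s_neg)
    diffs = np.array(diffs)
    test_res = wilcoxon_signed_rank_exact(diffs)
    return ModelSignificance(donor_ids, pairs, diffs, test_res, f"nested-{which}")


def component_report(
    fit: ENFit,
    feature_ids: list,
    p_values=None,
    q_flags=None,
    communities: dict | None = None,
) -> pd.DataFrame:
    """Ranked table of nonzero model components.

    One row per feature with a nonzero coefficient: the sµG-direction
    sign (positive = higher in sµG), |beta|, the univariate raw p and
    FDR discovery flag when provided, and the correlation-network
    community id. Sorted by discovery flag, then raw p, then |beta|
    descending.
    """
    if p_values is not None and len(p_values) != len(feature_ids):
        raise ValueError("p_values must align with feature_ids")
    if len(feature_ids) != fit.beta.size:
        raise ValueError("feature_ids must align with the fitted coefficients")
    rows = []
    for j, fid in enumerate(feature_ids):
        b = fit.beta[j]
        if b == 0:
            continue
        rows.append(
            {
                "feature": fid if isinstance(fid, str) else "|".join(map(str, fid)),
                "sign": int(np.sign(b)),
                "beta": float(b),
                "abs_beta": abs(float(b)),
                "p_value": float(p_values[j]) if p_values is not None else np.nan,
                "fdr_discovery": bool(q_flags[j]) if q_flags is not None else False,
                "community": communities.get(fid, -1) if communities else -1,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["feature", "sign", "beta", "abs_beta", "p_value", "fdr_discovery", "community"],
    )
    if df.empty:
        return df
    return df.sort_values(
        ["fdr_discovery", "p_value", "abs_beta"], ascending=[False, True, False]
    ).reset_index(drop=True)
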