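"""Elastic-net objective, coordinate descent, CV and significance."""

import numpy as np
import pytest

import cytogravity as cg
from cytogravity.en import DataError, PairingError, _cd_solve, _standardize
from cytogravity.stats import UndefinedTestError


class TestObjective:
    def test_zero_beta_gives_y_norm(self):
        Y = np.array([1.0, -2.0, 2.0])
        X = np.zeros((3, 2))
        assert cg.en_objective(X, Y, np.zeros(2), 0, 0) == pytest.approx(9.0)

    def test_perfect_fit_no_penalty(self):
        X = np.array([[1.0], [-1.0]])
        Y = np.array([1.0, -1.0])
        assert cg.en_objective(X, Y, np.array([1.0]), 0, 0) == 0.0

    def test_penalty_arithmetic(self):
        X = np.array([[1.0], [-1.0]])
        Y = np.array([1.0, -1.0])
        assert cg.en_objective(X, Y, np.array([1.0]), 2.0, 3.0) == pytest.approx(5.0)

    def test_literal_unsquared_norm_variant(self):
        X = np.zeros((2, 2))
        Y = np.zeros(2)
        beta = np.array([3.0, 4.0])
        assert cg.en_objective(X, Y, beta, 0, 1.0, squared_l2=False) == pytest.approx(5.0)
        assert cg.en_objective(X, Y, beta, 0, 1.0, squared_l2=True) == pytest.approx(25.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cg.en_objective(np.zeros((3, 2)), np.zeros(3), np.zeros(3), 0, 0)


class TestFit:
    def test_full_shrinkage_above_lambda_max(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 6))
        Y = rng.normal(size=20)
        l1max = cg.lambda_max(X, Y, mixing=1.0)
        fit = cg.fit_en(X, Y, l1max * 1.001, 0.0)
        assert fit.n_nonzero == 0
        fit2 = cg.fit_en(X, Y, l1max * 0.8, 0.0)
        assert fit2.n_nonzero > 0

    def test_unpenalized_single_predictor_is_ols(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        Y = 2.0 * x + rng.normal(0, 0.1, size=30)
        fit = cg.fit_en(x[:, None], Y, 0.0, 0.0)
        xs = (x - x.mean()) / x.std()
        ols = float(xs @ (Y - Y.mean()) / (xs @ xs))
        assert fit.beta[0] == pytest.approx(ols, rel=1e-8)
        assert fit.converged

    @pytest.mark.parametrize("l1,l2", [(0.5, 0.5), (2.0, 0.1), (0.0, 3.0), (4.0, 4.0)])
    def test_matches_bruteforce_grid_p2(self, l1, l2):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 2))
        Y = X @ np.array([1.2, -0.7]) + rng.normal(0, 0.3, size=15)
        fit = cg.fit_en(X, Y, l1, l2)
        Xs, _, _, _ = _standardize(X)
        yc = Y - Y.mean()
        grid = np.linspace(-3, 3, 121)
        best = np.inf
        for b1 in grid:
            for b2 in grid:
                beta = np.array([b1, b2])
                best = min(best, cg.en_objective(Xs, yc, beta, l1, l2))
        assert fit.objective <= best + 1e-6

    def test_objective_nonincreasing_across_sweeps(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 8))
        Y = rng.normal(size=12)
        Xs, _, _, _ = _standardize(X)
        yc = Y - Y.mean()
        G, c = Xs.T @ Xs, Xs.T @ yc
        objs = []
        for sweeps in range(1, 12):
            beta = np.zeros(8)
            _cd_solve(G, c, 1.0, 1.0, beta, 0.0, sweeps)
            objs.append(cg.en_objective(Xs, yc, beta, 1.0, 1.0))
        assert all(a >= b - 1e-10 for a, b in zip(objs, objs[1:]))

    def test_stationarity_at_exit(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(25, 10))
        Y = rng.normal(size=25)
        fit = cg.fit_en(X, Y, 1.5, 0.5, tol=1e-10)
        assert fit.converged
        assert fit.kkt_residual <= 10 * 1e-10

    def test_nonfinite_input_rejected(self):
        X = np.array([[1.0], [np.nan]])
        with pytest.raises(DataError):
            cg.fit_en(X, np.array([1.0, -1.0]), 0.1, 0.1)

    def test_solution_path_continuity(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 5))
        Y = X @ np.array([1.0, -1.0, 0.5, 0.0, 0.0]) + rng.normal(0, 0.2, size=30)
        lam = 2.0
        f1 = cg.fit_en(X, Y, 0.5 * lam, 0.5 * lam)
        f2 = cg.fit_en(X, Y, 0.5 * lam * 1.01, 0.5 * lam * 1.01)
        assert np.max(np.abs(f1.beta - f2.beta)) < 0.05


def _paired_data(n_donors=8, p=20, effect=2.0, seed=0, n_informative=5):
    rng = np.random.default_rng(seed)
    donors = np.repeat([f"D{i}" for i in range(n_donors)], 2)
    y = np.tile([-1.0, 1.0], n_donors)
    X = rng.normal(size=(2 * n_donors, p))
    X[:, :n_informative] += effect * y[:, None] / 2.0
    return X, y, donors


class TestCV:
    def test_separable_problem_reaches_zero_error(self):
        X, y, donors = _paired_data(effect=4.0, seed=6)
        cv = cg.cv_lambda_path(X, y, donors)
        assert cv.cv_error_mean[cv.idx_min] == 0.0
        assert cv.lambda_1se >= cv.lambda_min
        i = cv.idx_1se
        se = cv.cv_error_sd[cv.idx_min] / np.sqrt(len(cv.fold_donors))
        assert cv.cv_error_mean[i] <= cv.cv_error_mean[cv.idx_min] + se + 1e-12

    def test_constant_outcome_flagged_degenerate(self):
        X, _, donors = _paired_data(seed=7)
        y = np.ones_like(donors, dtype=float)
        cv = cg.cv_lambda_path(X, y, donors)
        assert cv.degenerate
        assert np.ptp(cv.cv_error_mean) == 0.0

    def test_shuffled_labels_give_chance_error(self):
        rng = np.random.default_rng(8)
        errs = []
        for rep in range(10):
            X, y, donors = _paired_data(effect=0.0, seed=100 + rep)
            cv = cg.cv_lambda_path(X, y, donors, n_lambda=20)
            errs.append(cv.cv_error_mean[-1])  # smallest penalty: pure overfit
        assert 0.3 < float(np.mean(errs)) < 0.7

    def test_missing_condition_is_pairing_error(self):
        X, y, donors = _paired_data(seed=9)
        with pytest.raises(PairingError):
            cg.cv_lambda_path(X[:-1], y[:-1], donors[:-1])


class TestSignificance:
    def test_eight_concordant_donors_hit_exact_floor(self):
        X, y, donors = _paired_data(effect=4.0, seed=10)
        cv = cg.cv_lambda_path(X, y, donors)
        sig = cg.model_significance(cv)
        assert (sig.differences > 0).all()
        assert sig.test.p_two_sided == pytest.approx(2 / 256)

    def test_nested_selection_detects_strong_signal(self):
        X, y, donors = _paired_data(effect=4.0, seed=14)
        sig = cg.nested_model_significance(X, y, donors, n_lambda=15)
        assert sig.test.p_two_sided == pytest.approx(2 / 256)
        assert sig.which_lambda == "nested-1se"

    def test_fully_shrunk_model_is_undefined(self):
        X, y, donors = _paired_data(effect=4.0, seed=11)
        cv = cg.cv_lambda_path(X, y, donors, lambda_grid=[1e9, 2e9])
        with pytest.raises(UndefinedTestError):
            cg.model_significance(cv)


class TestComponentReport:
    def test_zero_model_gives_empty_table(self):
        X, y, donors = _paired_data(seed=12)
        fit = cg.fit_en(X, y, 1e9, 1e9)
        table = cg.component_report(fit, [f"f{i}" for i in range(X.shape[1])])
        assert table.empty

    def test_informative_features_signed_correctly(self):
        X, y, donors = _paired_data(effect=4.0, seed=13)
        cv = cg.cv_lambda_path(X, y, donors)
        ids = [f"f{i}" for i in range(X.shape[1])]
        table = cg.component_report(cv.fit_1se, ids)
        informative = table[table.feature.isin(ids[:5])]
        assert len(informative) >= 4
        assert (informative.sign == 1).all()  # effect raises the +1 (sµG) rows
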