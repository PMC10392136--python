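"""Elastic-net pipeline: imputation, solver contracts, nested selection."""

import numpy as np
import pandas as pd
import pytest

from bcproteodyn.enpredict import (ENConfig, KNNFeatureImputer,
                                   NestedElasticNet, assemble_features,
                                   bootstrap_coefficients, fit_elastic_net,
                                   knn_impute, loocv_evaluate,
                                   paired_combo_test, select_top_k,
                                   tune_hyperparams, compare_layer_combos)
from bcproteodyn.io import OmicsMatrix

TINY = ENConfig(alpha_grid=(0.5, 1.0), n_lambdas=8, cv_folds=5, cv_reps=2,
                n_boot=20, k_max=15, tol=1e-4, seed=0)


def _om(vals, layer="protein"):
    vals = np.asarray(vals, dtype=float)
    return OmicsMatrix(layer, pd.DataFrame(
        vals, index=[f"F{i}" for i in range(vals.shape[0])],
        columns=[f"S{j}" for j in range(vals.shape[1])]))


class TestKnnImpute:
    def test_complete_matrix_identity(self):
        rng = np.random.default_rng(0)
        m = _om(rng.normal(20, 1, (10, 6)))
        out = knn_impute(m, k=3)
        assert out.values.equals(m.values)

    def test_twin_feature_supplies_value(self):
        # F0 and F1 identical except one missing cell: k=1 copies the twin
        vals = np.array([[1.0, 2.0, 3.0, np.nan],
                         [1.0, 2.0, 3.0, 4.0],
                         [9.0, 8.0, 7.0, 6.0]])
        out = knn_impute(_om(vals), k=1)
        assert out.values.at["F0", "S3"] == pytest.approx(4.0)

    def test_output_complete_and_observed_unchanged(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(20, 2, (30, 12))
        mask = rng.random(vals.shape) < 0.2
        vals_missing = vals.copy()
        vals_missing[mask] = np.nan
        out = knn_impute(_om(vals_missing), k=5)
        assert not out.values.isna().any().any()
        obs = ~mask
        assert np.allclose(out.values.to_numpy()[obs], vals[obs])

    def test_all_missing_feature_rejected(self):
        vals = np.array([[np.nan, np.nan], [1.0, 2.0]])
        with pytest.raises(ValueError, match="zero observed"):
            knn_impute(_om(vals))

    def test_sklearn_transformer_api(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (15, 8))
        X[rng.random(X.shape) < 0.15] = np.nan
        imp = KNNFeatureImputer(n_neighbors=3)
        out = imp.fit_transform(X)
        assert out.shape == X.shape and not np.isnan(out).any()


class TestElasticNetClosedForms:
    def test_critical_lambda_gives_null_model(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 10))
        y = rng.standard_normal(40)
        for alpha in (0.3, 1.0):
            lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / (40 * alpha)
            b0, coefs = fit_elastic_net(X, y, alpha, lam_max * 1.0001,
                                        tol=1e-10)
            assert np.allclose(coefs, 0.0, atol=1e-6)
            assert b0 == pytest.approx(y.mean(), abs=1e-9)

    def test_lasso_soft_threshold_on_orthonormal_design(self):
        rng = np.random.default_rng(4)
        n, p = 50, 8
        A = rng.standard_normal((n, p))
        A -= A.mean(axis=0)
        Q, _ = np.linalg.qr(A)
        X = np.sqrt(n) * Q               # X^T X = n I, columns centered
        y = rng.standard_normal(n)
        lam = 0.05
        _b0, coefs = fit_elastic_net(X, y, 1.0, lam, tol=1e-12)
        c = X.T @ (y - y.mean()) / n
        expected = np.sign(c) * np.maximum(np.abs(c) - lam, 0.0)
        assert np.allclose(coefs, expected, atol=1e-6)

    def test_unpenalized_limit_is_ols(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((30, 5))
        y = X @ np.arange(1.0, 6.0) + 0.1 * rng.standard_normal(30)
        _b0, coefs = fit_elastic_net(X, y, 1e-6, 1e-10, tol=1e-12)
        A = np.column_stack([np.ones(30), X])
        ols, *_ = np.linalg.lstsq(A, y, rcond=None)
        assert np.allclose(coefs, ols[1:], atol=1e-4)

    def test_zero_columns_intercept_only(self):
        b0, coefs = fit_elastic_net(np.empty((5, 0)), np.arange(5.0), 0.5, 0.1)
        assert coefs.size == 0 and b0 == pytest.approx(2.0)

    def test_objective_no_worse_than_zero_and_ols(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((25, 6))
        y = rng.standard_normal(25)
        alpha, lam = 0.7, 0.1

        def objective(b0, b):
            resid = y - b0 - X @ b
            return (resid @ resid / (2 * 25)
                    + lam * (alpha * np.abs(b).sum()
                             + (1 - alpha) / 2 * b @ b))

        b0, b = fit_elastic_net(X, y, alpha, lam, tol=1e-12)
        assert objective(b0, b) <= objective(y.mean(), np.zeros(6)) + 1e-12
        A = np.column_stack([np.ones(25), X])
        ols, *_ = np.linalg.lstsq(A, y, rcond=None)
        assert objective(b0, b) <= objective(ols[0], ols[1:]) + 1e-12

    def test_orthonormal_coefficients_shrink_with_lambda(self):
        rng = np.random.default_rng(7)
        n = 40
        A = rng.standard_normal((n, 5))
        A -= A.mean(axis=0)
        Q, _ = np.linalg.qr(A)
        X = np.sqrt(n) * Q
        y = X[:, 0] * 2 + X[:, 1] + 0.2 * rng.standard_normal(n)
        norms = []
        for lam in (0.01, 0.05, 0.2, 0.8):
            _b0, b = fit_elastic_net(X, y, 1.0, lam, tol=1e-10)
            norms.append(np.abs(b).sum())
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))


class TestTuning:
    def test_single_point_grid_returned(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((30, 10))
        y = rng.standard_normal(30)
        cfg = ENConfig(alpha_grid=(0.5,), n_lambdas=1, cv_folds=5, cv_reps=1,
                       n_boot=5, k_max=5)
        alpha, lam = tune_hyperparams(X, y, cfg, np.random.default_rng(0))
        assert alpha == 0.5
        lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / (30 * 0.5)
        assert lam == pytest.approx(lam_max)

    def test_planted_sparse_cv_error_near_noise_floor(self):
        rng = np.random.default_rng(9)
        n, p, sigma = 60, 200, 0.5
        X = rng.standard_normal((n, p))
        beta = np.zeros(p)
        beta[rng.choice(p, 5, replace=False)] = 1.0
        y = X @ beta + sigma * rng.standard_normal(n)
        cfg = ENConfig(alpha_grid=(0.5, 1.0), n_lambdas=15, cv_folds=5,
                       cv_reps=2, n_boot=10, k_max=10)
        alpha, lam = tune_hyperparams(X, y, cfg, np.random.default_rng(1))
        _b0, coefs = fit_elastic_net(X, y, alpha, lam)
        mse = np.mean((y - _b0 - X @ coefs) ** 2)
        assert mse < 2 * sigma ** 2

    def test_duplicated_rows_same_selection(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((20, 15))
        y = X[:, 0] + 0.3 * rng.standard_normal(20)
        cfg = ENConfig(alpha_grid=(0.5, 1.0), n_lambdas=8, cv_folds=5,
                       cv_reps=2, n_boot=5, k_max=5)
        pick1 = tune_hyperparams(X, y, cfg, np.random.default_rng(2))
        pick2 = tune_hyperparams(X, y, cfg, np.random.default_rng(2))
        assert pick1 == pick2


class TestBootstrap:
    def test_full_subsample_single_run_equals_plain_fit(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((30, 10))
        y = X[:, 0] + 0.1 * rng.standard_normal(30)
        cfg = ENConfig(alpha_grid=(1.0,), n_boot=1, subsample_fraction=1.0,
                       n_lambdas=5, cv_folds=5, cv_reps=1, k_max=5)
        mean, runs, ranking = bootstrap_coefficients(
            X, y, 1.0, 0.05, cfg, np.random.default_rng(0))
        _b0, direct = fit_elastic_net(X, y, 1.0, 0.05, tol=cfg.tol)
        assert np.allclose(mean, direct, atol=1e-8)
        assert ranking[0] == 0

    def test_zero_response_zero_coefficients(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((20, 6))
        cfg = ENConfig(n_boot=10, n_lambdas=5, cv_folds=5, cv_reps=1, k_max=5)
        mean, *_ = bootstrap_coefficients(X, np.zeros(20), 0.5, 0.1, cfg,
                                          np.random.default_rng(0))
        assert np.allclose(mean, 0.0)

    def test_planted_predictors_rank_high(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n, p = 60, 300
            X = rng.standard_normal((n, p))
            truth = rng.choice(p, 5, replace=False)
            beta = np.zeros(p)
            beta[truth] = 1.0
            y = X @ beta + 0.5 * rng.standard_normal(n)
            cfg = ENConfig(alpha_grid=(1.0,), n_lambdas=10, cv_folds=5,
                           cv_reps=1, n_boot=30, k_max=10)
            _a, lam = tune_hyperparams(X, y, cfg, np.random.default_rng(seed))
            _m, _r, ranking = bootstrap_coefficients(
                X, y, 1.0, lam, cfg, np.random.default_rng(seed))
            if set(truth) <= set(ranking[:10]):
                hits += 1
        assert hits >= 9

    def test_tiny_subsample_rejected(self):
        cfg = ENConfig(subsample_fraction=0.5, n_boot=2, n_lambdas=5,
                       cv_folds=5, cv_reps=1, k_max=5)
        with pytest.raises(ValueError, match="subsample"):
            bootstrap_coefficients(np.ones((4, 2)), np.arange(4.0), 0.5, 0.1,
                                   cfg, np.random.default_rng(0))


class TestSelectTopK:
    def test_k_one_when_single_predictor_suffices(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((50, 10))
        y = 3 * X[:, 4] + 0.01 * rng.standard_normal(50)
        ranking = np.array([4] + [j for j in range(10) if j != 4])
        k = select_top_k(X, y, ranking, TINY, np.random.default_rng(0))
        assert k == 1

    def test_se_zero_returns_argmin(self):
        # noiseless exact fit at k=2: CV error collapses to float-epsilon
        # scale there, so the 1-SE band cannot admit any smaller k
        rng = np.random.default_rng(14)
        X = rng.standard_normal((40, 6))
        y = X[:, 0] + 2 * X[:, 1]
        ranking = np.arange(6)
        k = select_top_k(X, y, ranking, TINY, np.random.default_rng(0))
        assert k in (2, 3)

    def test_recovers_planted_support_size_scale(self):
        rng = np.random.default_rng(15)
        n, p = 60, 40
        X = rng.standard_normal((n, p))
        y = X[:, :5] @ np.ones(5) + 0.1 * rng.standard_normal(n)
        ranking = np.arange(p)       # true predictors ranked first
        k = select_top_k(X, y, ranking, TINY, np.random.default_rng(1))
        assert 4 <= k <= 8


class TestLoocvEvaluate:
    def test_noiseless_linear_response_near_perfect(self):
        rng = np.random.default_rng(16)
        n, p = 24, 30
        X = rng.standard_normal((n, p))
        y = X[:, 0] + 2 * X[:, 1]
        Xdf = pd.DataFrame(X, index=[f"L{i}" for i in range(n)],
                           columns=[f"F{j}" for j in range(p)])
        res = loocv_evaluate(Xdf, pd.Series(y, index=Xdf.index), TINY,
                             drug="toy", seed=0)
        assert res.predictive_power > 0.99
        assert res.valid

    def test_constant_response_rejected(self):
        X = pd.DataFrame(np.random.default_rng(17).standard_normal((12, 4)))
        with pytest.raises(ValueError, match="constant"):
            loocv_evaluate(X, pd.Series(np.ones(12)), TINY)

    def test_too_few_lines_marks_invalid(self):
        X = pd.DataFrame(np.random.default_rng(18).standard_normal((6, 4)))
        res = loocv_evaluate(X, pd.Series(np.arange(6.0)), TINY, drug="d")
        assert not res.valid and np.isnan(res.predictive_power)

    def test_reproducible_at_fixed_seed(self):
        rng = np.random.default_rng(19)
        X = pd.DataFrame(rng.standard_normal((14, 10)))
        y = pd.Series(X[0] + 0.2 * rng.standard_normal(14))
        a = loocv_evaluate(X, y, TINY, seed=5)
        b = loocv_evaluate(X, y, TINY, seed=5)
        assert a.predictive_power == b.predictive_power
        assert a.top_k == b.top_k and a.k == b.k


class TestLayerCombos:
    def test_assembly_tags_and_mutation_mask(self, cohort):
        matrices, ann, resp, _truth = cohort
        from bcproteodyn.qc import average_replicates
        avg = knn_impute(average_replicates(matrices["D"], ann), k=5)
        X, mask = assemble_features({"M": matrices["M"], "D": avg},
                                    resp.cell_lines)
        assert X.shape[0] == len(resp.cell_lines)
        assert mask.sum() == matrices["M"].shape[0]
        assert all(c.startswith(("M:", "D:")) for c in X.columns)
        assert not X.isna().any().any()

    def test_unimputed_layer_rejected(self, cohort):
        matrices, ann, resp, _truth = cohort
        from bcproteodyn.qc import average_replicates
        avg = average_replicates(matrices["D"], ann)
        with pytest.raises(ValueError, match="impute"):
            assemble_features({"D": avg}, resp.cell_lines)

    def test_single_drug_single_combo_one_row(self):
        rng = np.random.default_rng(20)
        prot = _om(rng.normal(20, 1, (20, 14)))
        prot.values.columns = [f"L{i}" for i in range(14)]
        y = prot.values.iloc[0] + 0.1 * rng.standard_normal(14)
        from bcproteodyn.io import DrugResponseTable
        resp = DrugResponseTable(pd.DataFrame({"d1": y}))
        table = compare_layer_combos({"D": prot}, resp, ["d1"], ["D"],
                                     TINY, seed=0)
        assert len(table) == 1
        assert table.loc[0, "predictive_power"] > 0.8

    def test_paired_test_on_identical_combos_is_degenerate(self):
        table = pd.DataFrame({
            "drug": ["a", "b", "c", "a", "b", "c"],
            "combo": ["D", "D", "D", "E", "E", "E"],
            "predictive_power": [0.5, 0.65, 0.7, 0.4, 0.5, 0.62],
            "n_lines": [20] * 6, "valid": [True] * 6,
        })
        t, _p = paired_combo_test(table, "D", "E")
        assert t > 0
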