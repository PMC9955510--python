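import numpy as np
import pytest

from radtx.io import ExpressionMatrix
from radtx.pmetaomics import (
    PMetaomicsModel,
    PMetaomicsSignature,
    apply_models,
    evaluate_model,
    fit_lasso_loocv,
    select_pmetaomics,
)

from conftest import make_expr


class TestFitLassoLoocv:
    def test_noiseless_support_recovery(self, rng):
        X = rng.normal(size=(20, 10))
        y = 3.0 * X[:, 5] - 2.0 * X[:, 7]
        m = fit_lasso_loocv(X, y)
        support = {i for i, c in enumerate(m.coef) if c != 0}
        assert support == {5, 7}
        assert m.diagnostics["r_squared"] >= 0.99

    def test_lambda_beyond_max_kills_all_coefficients(self, rng):
        X = rng.normal(size=(15, 8))
        y = X[:, 0] + rng.normal(size=15)
        Z = (X - X.mean(0)) / X.std(0)
        lam_max = np.abs(Z.T @ (y - y.mean())).max() / 15
        m = fit_lasso_loocv(X, y, lambda_grid=np.array([lam_max * 2, lam_max * 4]))
        assert np.all(m.coef == 0)
        assert m.diagnostics["r_squared"] == pytest.approx(0.0, abs=1e-12)

    def test_null_response_flat_model(self):
        cv_ratios, r2s = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(24, 30))
            y = rng.normal(size=24)
            m = fit_lasso_loocv(X, y)
            cv_mse = ((m.cv_predictions - y) ** 2).mean()
            cv_ratios.append(cv_mse / y.var())
            r2s.append(m.diagnostics["r_squared"])
        assert 0.7 <= np.median(cv_ratios) <= 1.5
        assert np.median(r2s) <= 0.3

    def test_matches_ols_at_tiny_lambda(self, rng):
        X = rng.normal(size=(50, 4))
        beta = np.array([1.0, -2.0, 0.5, 3.0])
        y = X @ beta + 0.01 * rng.normal(size=50)
        Z = (X - X.mean(0)) / X.std(0)
        m = fit_lasso_loocv(X, y, lambda_grid=np.array([1e-8]))
        ols = np.linalg.lstsq(
            np.column_stack([np.ones(50), Z]), y, rcond=None
        )[0][1:]
        np.testing.assert_allclose(m.coef, ols, atol=1e-6)

    def test_loocv_invariant_to_sample_order(self, rng):
        X = rng.normal(size=(16, 12))
        y = X[:, 2] - X[:, 9] + 0.3 * rng.normal(size=16)
        m1 = fit_lasso_loocv(X, y)
        perm = rng.permutation(16)
        m2 = fit_lasso_loocv(X[perm], y[perm])
        assert m1.lambda_ == m2.lambda_
        np.testing.assert_allclose(m1.coef, m2.coef, atol=1e-8)

    def test_constant_response_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            fit_lasso_loocv(rng.normal(size=(10, 4)), np.ones(10))


class TestEvaluateModel:
    def _identity_model(self, p):
        return PMetaomicsModel(
            "m", [f"g{i}" for i in range(p)], 0.0, np.zeros(p), 0.1,
            np.zeros(p), np.ones(p),
        )

    def test_perfect_and_mean_predictions(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        m = self._identity_model(3)
        m.intercept = float(y.mean())
        diag = evaluate_model(m, X, y)  # predicts mean(y) everywhere
        assert diag["r_squared"] == pytest.approx(0.0, abs=1e-12)

        m2 = PMetaomicsModel("m", ["g0"], 0.0, np.array([1.0]), 0.1,
                             np.array([0.0]), np.array([1.0]))
        diag2 = evaluate_model(m2, y[:, None], y)  # prediction == y
        assert diag2["r_squared"] == pytest.approx(1.0)
        assert diag2["nrmse"] == pytest.approx(0.0, abs=1e-12)
        assert diag2["pearson_r"] == pytest.approx(1.0)

    def test_hand_computed_four_point_r2(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        pred_x = np.array([1.0, 3.0, 2.0, 5.0])
        m = PMetaomicsModel("m", ["g0"], 0.0, np.array([1.0]), 0.1,
                            np.array([0.0]), np.array([1.0]))
        diag = evaluate_model(m, pred_x[:, None], y)
        ss_res = float(((y - pred_x) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        assert diag["r_squared"] == pytest.approx(1 - ss_res / ss_tot)
        assert diag["nrmse"] == pytest.approx(np.sqrt(ss_res / 4) / 5.0)


class TestSelectPmetaomics:
    def _expr(self, rng, p=6, n=12):
        return make_expr(rng.normal(size=(p, n)))

    def test_low_r2_rejected_with_reason(self, rng):
        expr = self._expr(rng)
        X = expr.values.T
        good = fit_lasso_loocv(X, X[:, 0] * 2.0, expr.gene_ids, "good")
        bad = fit_lasso_loocv(X, rng.normal(size=12) * 5, expr.gene_ids, "bad")
        bad.diagnostics["r_squared"] = 0.5
        sig = select_pmetaomics([good, bad], expr, r2_threshold=0.70)
        assert sig.feature_ids == ["good"]
        assert ("bad", "low_r2") in sig.rejected

    def test_uncorrelated_prediction_rejected(self, rng):
        expr = self._expr(rng)
        flat = PMetaomicsModel(
            "flat", list(expr.gene_ids), 1.0, np.zeros(expr.n_genes), 0.1,
            np.zeros(expr.n_genes), np.ones(expr.n_genes),
            diagnostics={"r_squared": 0.95},
        )
        sig = select_pmetaomics([flat], expr)
        assert ("flat", "no_gene_correlation") in sig.rejected


class TestApplyModels:
    def test_linear_form_on_zscored_genes(self, rng):
        expr = make_expr(rng.normal(size=(3, 10)))
        m = PMetaomicsModel(
            "m", list(expr.gene_ids), 0.0, np.array([2.0, 0.0, 0.0]), 0.1,
            np.zeros(3), np.ones(3),
        )
        sig = PMetaomicsSignature([m], [], list(expr.gene_ids), 0.7)
        out = apply_models(sig, expr)
        g1 = expr.values[0]
        z = (g1 - g1.mean()) / g1.std()
        np.testing.assert_allclose(out["m"].to_numpy(), 2.0 * z, atol=1e-12)

    def test_zero_model_gives_intercept_column(self, rng):
        expr = make_expr(rng.normal(size=(2, 5)))
        m = PMetaomicsModel("m", list(expr.gene_ids), 3.5, np.zeros(2), 0.1,
                            np.zeros(2), np.ones(2))
        sig = PMetaomicsSignature([m], [], list(expr.gene_ids), 0.7)
        out = apply_models(sig, expr)
        np.testing.assert_array_equal(out["m"].to_numpy(), np.full(5, 3.5))

    def test_missing_gene_error_and_drop_flag(self, rng):
        expr = make_expr(rng.normal(size=(2, 5)))
        m = PMetaomicsModel("m", ["g0", "missing"], 0.0, np.array([1.0, 1.0]), 0.1,
                            np.zeros(2), np.ones(2))
        sig = PMetaomicsSignature([m], [], ["g0", "missing"], 0.7)
        with pytest.raises(KeyError, match="missing"):
            apply_models(sig, expr)
        out = apply_models(sig, expr, drop_incomplete_models=True)
        assert out.shape[1] == 0

    def test_serialization_round_trip_identical_coefficients(self, rng):
        X = rng.normal(size=(14, 6))
        y = X[:, 1] - 0.5 * X[:, 4] + 0.1 * rng.normal(size=14)
        m = fit_lasso_loocv(X, y, feature_id="wavelet_LLH_glcm_f0001")
        sig = PMetaomicsSignature([m], [("x", "low_r2")], m.gene_ids, 0.7)
        back = PMetaomicsSignature.from_dict(sig.to_dict())
        np.testing.assert_array_equal(back.models[0].coef, m.coef)
        assert back.models[0].intercept == m.intercept
        assert back.models[0].lambda_ == m.lambda_
        assert back.rejected == [("x", "low_r2")]
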