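"""Sparse MLR-EM: OLS limit, pruning behavior, post-selection inference and
prediction contracts."""

import numpy as np
import pandas as pd
import pytest

from lipistage import (
    coefficient_ttests,
    fit_mlrem,
    predict,
    sparsity_sweep,
)
from lipistage.errors import InputError, ParameterError


def _random_problem(seed, n=40, p=5, noise=0.5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    w = rng.normal(size=p)
    y = X @ w + noise * rng.normal(size=n)
    return X, y


class TestOlsLimit:
    def test_single_column_exact_relation(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        model = fit_mlrem(X, y, beta_sparsity=0.0)
        _, raw = model.raw_coefficients()
        assert raw["x0"] == pytest.approx(1.0)
        assert np.allclose(predict(model, X), y, atol=1e-8)

    @pytest.mark.parametrize("seed", range(20))
    def test_beta_zero_matches_closed_form_ols(self, seed):
        X, y = _random_problem(seed)
        model = fit_mlrem(X, y, beta_sparsity=0.0)
        design = np.column_stack([np.ones(len(y)), X])
        ols = np.linalg.lstsq(design, y, rcond=None)[0]
        intercept, raw = model.raw_coefficients()
        got = np.array([raw[f"x{j}"] for j in range(X.shape[1])])
        assert np.allclose(got, ols[1:], rtol=1e-6)
        assert intercept == pytest.approx(ols[0], rel=1e-6, abs=1e-9)

    def test_small_beta_close_to_ols(self):
        X, y = _random_problem(3)
        model = fit_mlrem(X, y, beta_sparsity=1e-8)
        ols = fit_mlrem(X, y, beta_sparsity=0.0)
        for f in ols.coefficients:
            assert model.coefficients[f] == pytest.approx(
                ols.coefficients[f], abs=1e-4)


class TestSparsity:
    def test_single_informative_feature_recovered(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(50, 5))
            y = 3.0 * X[:, 0] + 0.5 * rng.normal(size=50)
            model = fit_mlrem(X, y, beta_sparsity=1.0)
            hits += model.selected_features == ["x0"]
        assert hits >= 19

    def test_fixed_point_satisfies_lasso_stationarity(self):
        """A converged nonzero coefficient set must satisfy the L1
        stationarity condition Xᵀ(y−Xw)/n = β·sign(w) on standardized data —
        cross-checked against scikit-learn's lasso on the same problem."""
        from sklearn.linear_model import Lasso

        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 8))
        y = X @ np.array([2, -1.5, 1, 0, 0, 0, 0, 0.0]) + 0.3 * rng.normal(size=60)
        beta = 0.3
        model = fit_mlrem(X, y, beta_sparsity=beta)
        Xs = (X - X.mean(0)) / X.std(0)
        yc = y - y.mean()
        # independent solver: sklearn lasso objective 1/(2n)||y-Xw||² + a||w||₁
        ref = Lasso(alpha=beta, fit_intercept=False, tol=1e-12,
                    max_iter=100000).fit(Xs, yc)
        sel_ref = {f"x{j}" for j in np.flatnonzero(np.abs(ref.coef_) > 1e-6)}
        assert set(model.selected_features) == sel_ref
        got = np.array([model.coefficients.get(f"x{j}", 0.0) for j in range(8)])
        assert np.allclose(got, ref.coef_, atol=1e-4)

    def test_identical_columns_keep_equal_weights(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        X = np.column_stack([x, x, rng.normal(size=40)])
        y = 2 * x + 0.1 * rng.normal(size=40)
        model = fit_mlrem(X, y, beta_sparsity=0.5)
        if "x0" in model.coefficients and "x1" in model.coefficients:
            assert model.coefficients["x0"] == pytest.approx(
                model.coefficients["x1"], rel=1e-6)

    def test_sweep_counts_non_increasing_on_fixture(self, coded_three_class):
        sweep = sparsity_sweep(coded_three_class.X, coded_three_class.y,
                               [0.05, 0.12, 0.35, 0.6])
        counts = sweep.n_selected()
        assert all(b >= a for a, b in zip(counts[1:], counts))

    def test_sweep_beta_zero_keeps_all_features(self):
        X, y = _random_problem(5, n=40, p=6)
        sweep = sparsity_sweep(X, y, [0.0])
        assert sweep.entries[0][1] == 6

    def test_huge_beta_gives_flagged_intercept_only_model(self):
        X, y = _random_problem(1)
        model = fit_mlrem(X, y, beta_sparsity=1e6)
        assert model.degenerate
        assert model.selected_features == []
        assert np.allclose(predict(model, X), y.mean())

    def test_sweep_rejects_unsorted_betas(self):
        X, y = _random_problem(1)
        with pytest.raises(ParameterError):
            sparsity_sweep(X, y, [0.5, 0.2])


class TestInference:
    def test_hand_computed_slope_and_t(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([2.1, 3.9, 6.2, 7.8])
        t, p = coefficient_ttests(X, y)
        # hand OLS: Sxx=5, Sxy=9.70 → slope 1.94; SSE=0.082 → SE≈0.0906
        assert t["x0"] == pytest.approx(21.4, rel=5e-3)
        assert 0 < p["x0"] < 0.01

    def test_exact_fit_flagged_with_smallest_p(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = 2.0 * X[:, 0] + 1.0
        model = fit_mlrem(X, y, beta_sparsity=0.0)
        assert model.exact_fit
        assert model.p_values["x0"] == np.finfo(float).tiny

    def test_orthogonal_predictor_gets_t_zero(self):
        X = np.array([[1.0, -1.0], [1.0, 1.0], [-1.0, -1.0], [-1.0, 1.0],
                      [1.0, -1.0], [-1.0, 1.0]])
        y = X[:, 0] * 2.0 + np.array([0.1, -0.1, 0.05, -0.05, -0.1, 0.1])
        t, p = coefficient_ttests(X, y)
        assert abs(t["x1"]) < abs(t["x0"])

    def test_too_few_samples_rejected(self):
        with pytest.raises(InputError):
            coefficient_ttests(np.ones((3, 2)), [1.0, 2.0, 3.0])


class TestPredictionContracts:
    def test_scale_equivariance(self):
        X, y = _random_problem(2)
        model = fit_mlrem(X, y, beta_sparsity=0.2)
        X2 = X.copy()
        X2[:, 0] *= 37.0
        model2 = fit_mlrem(X2, y, beta_sparsity=0.2)
        assert np.allclose(predict(model, X), predict(model2, X2), atol=1e-6)

    def test_pruned_features_do_not_affect_predictions(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(50, 6)),
                         columns=[f"F{j}" for j in range(6)])
        y = 3 * X["F0"] + 0.3 * rng.normal(size=50)
        model = fit_mlrem(X, y, beta_sparsity=1.0)
        pruned = [c for c in X.columns if c not in model.selected_features]
        assert pruned
        X_perturbed = X.copy()
        X_perturbed[pruned] = rng.normal(size=(50, len(pruned)))
        assert np.allclose(predict(model, X), predict(model, X_perturbed))

    def test_missing_selected_column_named_in_error(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(30, 2)),
                         columns=["a", "b"])
        y = X["a"] * 2
        model = fit_mlrem(X, y, beta_sparsity=0.1)
        with pytest.raises(InputError, match="a"):
            predict(model, X[["b"]])

    def test_nonfinite_input_rejected(self):
        X, y = _random_problem(0)
        X[0, 0] = np.inf
        with pytest.raises(InputError):
            fit_mlrem(X, y, beta_sparsity=0.1)

    def test_serialization_roundtrip(self, tmp_path):
        X, y = _random_problem(6)
        model = fit_mlrem(X, y, beta_sparsity=0.3)
        path = tmp_path / "model.json"
        model.to_json(path)
        import json
        data = json.loads(path.read_text())
        assert data["beta_sparsity"] == 0.3
        assert set(data["coefficients"]) == set(model.selected_features)
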