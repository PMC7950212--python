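"""Lasso training, one-SE selection, pruning, prediction, evaluation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ciffrac import model as md
from ciffrac.features import FEATURE_NAMES
from ciffrac.preprocess import ModelMatrix, min_max_normalize


def make_matrix(X: pd.DataFrame, y: pd.Series) -> ModelMatrix:
    bounds = pd.DataFrame({"min": X.min(axis=0), "max": X.max(axis=0)})
    return ModelMatrix(X=X, y=y, bounds=bounds)


def synthetic_design(n: int, seed: int, names=None) -> pd.DataFrame:
    """Independent uniform features in [0,1], named like real predictors."""
    names = list(FEATURE_NAMES) if names is None else names
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.uniform(size=(n, len(names))), columns=names)


class TestFitLassoCV:
    def test_noiseless_sparse_recovery_at_densest_lambda(self):
        X = synthetic_design(1000, seed=1)
        truth = {"Charge": 12.0, "Hydrophobicity": -8.0, "a-Index": 5.0}
        y = pd.Series(50.0 + sum(w * X[f] for f, w in truth.items()), index=X.index)
        spec, cv = md.fit_lasso_cv(make_matrix(X, y), seed=2)
        densest = cv.densest_coefficients
        support = set(densest[densest.abs() > 0.05].index)
        assert support == set(truth)
        for f, w in truth.items():
            assert densest[f] == pytest.approx(w, rel=0.05)

    def test_constant_response_gives_intercept_only(self):
        X = synthetic_design(50, seed=3)
        y = pd.Series(np.full(50, 80.0), index=X.index)
        with pytest.warns(UserWarning, match="constant response"):
            spec, _ = md.fit_lasso_cv(make_matrix(X, y), folds=5, seed=0)
        assert spec.coefficients == {} and spec.intercept == pytest.approx(80.0)

    def test_all_coefficients_zero_at_lambda_max(self):
        X = synthetic_design(200, seed=4)
        rng = np.random.default_rng(5)
        y = pd.Series(75 + 10 * X["Charge"] + rng.normal(0, 1, 200), index=X.index)
        _, cv = md.fit_lasso_cv(make_matrix(X, y), seed=6)
        assert (cv.coef_path.iloc[:, 0] == 0).all()

    def test_one_se_lambda_at_least_minimizer(self):
        for seed in range(3):
            X = synthetic_design(300, seed=seed)
            rng = np.random.default_rng(seed + 100)
            y = pd.Series(
                70 + 15 * X["Charge"] - 9 * X["Polar No."] + rng.normal(0, 2, 300),
                index=X.index,
            )
            _, cv = md.fit_lasso_cv(make_matrix(X, y), seed=seed)
            assert cv.alpha_1se >= cv.alpha_min

    def test_support_size_non_increasing_along_lambda_path(self):
        X = synthetic_design(400, seed=8)
        rng = np.random.default_rng(9)
        y = pd.Series(
            70 + 12 * X["Charge"] - 7 * X["Tiny mole %"] + 4 * X["a-Index"]
            + rng.normal(0, 1.5, 400),
            index=X.index,
        )
        _, cv = md.fit_lasso_cv(make_matrix(X, y), seed=10)
        nnz = (cv.coef_path.to_numpy() != 0).sum(axis=0)  # alphas descending
        assert np.all(np.diff(nnz) >= 0)


class TestPrune:
    def test_small_coefficient_dropped_and_refit(self):
        X = synthetic_design(500, seed=11, names=["Charge", "Instability index"])
        rng = np.random.default_rng(12)
        y = pd.Series(
            70 + 10 * X["Charge"] + 0.01 * X["Instability index"]
            + rng.normal(0, 0.5, 500),
            index=X.index,
        )
        matrix = make_matrix(X, y)
        spec, _ = md.fit_lasso_cv(matrix, seed=13)
        spec = md.ElutionModelSpec(
            intercept=spec.intercept,
            coefficients={"Charge": 10.0, "Instability index": 0.01},
            lam=spec.lam, normalization_bounds=matrix.bounds,
        )
        pruned = md.prune_minimal_features(spec, matrix, threshold=0.5,
                                           seed=13, cv_guard=False)
        assert set(pruned.coefficients) == {"Charge"}
        assert pruned.coefficients["Charge"] == pytest.approx(10.0, rel=0.05)

    def test_threshold_zero_is_identity(self):
        X = synthetic_design(300, seed=14)
        rng = np.random.default_rng(15)
        y = pd.Series(75 + 8 * X["Charge"] + rng.normal(0, 1, 300), index=X.index)
        matrix = make_matrix(X, y)
        spec, _ = md.fit_lasso_cv(matrix, seed=16)
        pruned = md.prune_minimal_features(spec, matrix, threshold=0.0, seed=16)
        assert pruned.coefficients == spec.coefficients

    def test_recovers_dominant_features_of_reference_model(self):
        # reference-model response on 9 informative + 14 inert features,
        # noise sd 3.82: the 5 largest-|coefficient| features survive pruning
        truth = md.REFERENCE_MODEL.coefficients
        top5 = set(sorted(truth, key=lambda f: abs(truth[f]), reverse=True)[:5])
        hits = 0
        runs = 20
        for seed in range(runs):
            X = synthetic_design(3000, seed=seed)
            rng = np.random.default_rng(1000 + seed)
            signal = sum(w * X[f] for f, w in truth.items())
            y = pd.Series(76.62 + signal + rng.normal(0, 3.82, len(X)), index=X.index)
            matrix = make_matrix(X, y)
            spec, _ = md.fit_lasso_cv(matrix, seed=seed)
            pruned = md.prune_minimal_features(spec, matrix, seed=seed)
            if top5 <= set(pruned.coefficients):
                hits += 1
        assert hits >= 0.95 * runs


class TestPredict:
    def test_reference_intercept_at_zero_features(self):
        zeros = pd.Series(0.0, index=list(FEATURE_NAMES))
        value = md.predict(md.REFERENCE_MODEL, zeros, normalized=True)
        assert value == pytest.approx(76.62)

    def test_zero_coefficient_spec_is_constant(self):
        spec = md.ElutionModelSpec(intercept=81.5, coefficients={})
        X = synthetic_design(10, seed=17)
        np.testing.assert_allclose(md.predict(spec, X, normalized=True), 81.5)

    def test_matches_dot_product_oracle(self):
        rng = np.random.default_rng(18)
        X_raw = synthetic_design(100, seed=19) * 50.0
        _, bounds = min_max_normalize(X_raw)
        coefs = {f: float(rng.normal()) for f in list(FEATURE_NAMES)[:7]}
        spec = md.ElutionModelSpec(
            intercept=76.0, coefficients=coefs, normalization_bounds=bounds
        )
        pred = md.predict(spec, X_raw)
        for i in range(len(X_raw)):
            expected = 76.0
            for f, w in coefs.items():
                lo, hi = bounds.loc[f, "min"], bounds.loc[f, "max"]
                expected += w * (X_raw.iloc[i][f] - lo) / (hi - lo)
            assert pred[i] == pytest.approx(expected, abs=1e-9)

    def test_missing_feature_and_bounds_errors(self):
        spec = md.ElutionModelSpec(intercept=76.62, coefficients={"Charge": 1.0})
        with pytest.raises(ValueError, match="missing required features"):
            md.predict(spec, pd.DataFrame({"pI": [7.0]}), normalized=True)
        with pytest.raises(ValueError, match="bounds"):
            md.predict(spec, pd.DataFrame({"Charge": [1.0]}))

    def test_snap_to_fractions(self):
        snapped = md.snap_to_fractions(np.array([91.0, 86.9, 72.4, 40.0, 99.0]))
        np.testing.assert_array_equal(snapped, [90, 85, 70, 70, 90])


class TestEvaluate:
    def _spec_identity(self):
        return md.ElutionModelSpec(intercept=0.0, coefficients={"Charge": 1.0})

    def test_perfect_predictions(self):
        X = pd.DataFrame({"Charge": [90.0, 85.0, 70.0, 70.0]})
        y = pd.Series([90.0, 85.0, 70.0, 70.0])
        report = md.evaluate(self._spec_identity(), X, y, normalized=True)
        assert report.accuracy == 100.0
        assert report.rmse == 0.0 and report.r2 == pytest.approx(1.0)

    def test_uniform_out_of_band_error(self):
        X = pd.DataFrame({"Charge": [96.0, 91.0, 76.0]})
        y = pd.Series([90.0, 85.0, 70.0])
        report = md.evaluate(self._spec_identity(), X, y, normalized=True)
        assert report.accuracy == 0.0
        assert report.rmse == pytest.approx(6.0)

    def test_hand_built_six_point_half_accuracy(self):
        # residuals: +2, -4 (within band), +8, -9, +12 (out), 0 (within)
        X = pd.DataFrame({"Charge": [92.0, 81.0, 98.0, 66.0, 82.0, 70.0]})
        y = pd.Series([90.0, 85.0, 90.0, 75.0, 70.0, 70.0])
        report = md.evaluate(self._spec_identity(), X, y, tolerance=5.0,
                             normalized=True)
        assert report.pooled_accuracy == pytest.approx(50.0)

    def test_tolerance_limits(self):
        rng = np.random.default_rng(20)
        X = pd.DataFrame({"Charge": rng.uniform(60, 100, 50)})
        y = pd.Series(rng.choice([70.0, 75.0, 80.0, 85.0, 90.0], 50))
        spec = self._spec_identity()
        assert md.evaluate(spec, X, y, tolerance=1e9, normalized=True).accuracy == 100.0
        assert md.evaluate(spec, X, y, tolerance=0.0, normalized=True).accuracy == 0.0

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            md.evaluate(self._spec_identity(), pd.DataFrame({"Charge": []}),
                        pd.Series(dtype=float), normalized=True)


class TestSpecValidation:
    def test_reference_model_is_table_constant(self):
        spec = md.REFERENCE_MODEL
        assert spec.intercept == 76.62
        assert spec.coefficients["Charged No."] == -21.05
        assert len(spec.coefficients) == 9
        assert spec.provenance == "published_reference"

    def test_unknown_feature_name_rejected(self):
        with pytest.raises(ValueError, match="unknown feature"):
            md.ElutionModelSpec(intercept=0.0, coefficients={"Molecular weight": 1.0})
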