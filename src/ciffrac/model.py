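"""Lasso model of peptide elution concentration, and its evaluation.

The response is the isopropanol concentration (%) at which a peptide elutes
from carboxylate-modified magnetic beads; the predictors are the 23
Max-Min-normalized physicochemical features. An L1-penalized least-squares
fit with tenfold cross-validation selects the penalty by the one-standard-
error rule, and features that contribute minimally are pruned before the
final refit. The published nine-variable model ships as
:data:`REFERENCE_MODEL`.

Features are NOT re-standardized inside the Lasso: they enter exactly as
Max-Min normalized, so coefficients are in isopropanol % per normalized-
feature unit. Tools that standardize internally (e.g. glmnet defaults)
report coefficients on a different scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import KFold

from .features import FEATURE_NAMES
from .preprocess import ELUTION_CONCENTRATIONS, ModelMatrix, min_max_normalize

log = logging.getLogger(__name__)

_LASSO_KW = dict(max_iter=50_000, tol=1e-8)


@dataclass(frozen=True)
class ElutionModelSpec:
    """Intercept + named coefficients of a linear elution model.

    Coefficients apply to Max-Min-normalized features; ``normalization_bounds``
    (per-feature raw min/max) must be present to predict from raw features.
    ``provenance`` is "trained" or "published_reference".
    """

    intercept: float
    coefficients: dict
    lam: float | None = None
    normalization_bounds: pd.DataFrame | None = None
    provenance: str = "trained"

    def __post_init__(self) -> None:
        unknown = set(self.coefficients) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature names in coefficients: {sorted(unknown)}")

    @property
    def feature_names(self) -> list:
        return list(self.coefficients)

    def with_bounds(self, bounds: pd.DataFrame) -> "ElutionModelSpec":
        return replace(self, normalization_bounds=bounds)


#: The published nine-variable elution model (coefficients in isopropanol %
#: per normalized-feature unit). Normalization bounds are not published;
#: attach population-derived bounds via ``with_bounds`` before predicting.
REFERENCE_MODEL = ElutionModelSpec(
    intercept=76.62,
    coefficients={
        "Charged No.": -21.05,
        "Charge": 11.87,
        "Hydrophobicity": 8.30,
        "Polar No.": -6.82,
        "Acidic mole %": -5.34,
        "a-Index": 5.27,
        "Tiny mole %": -3.83,
        "Nonpolar mole %": 0.85,
        "Instability index": -0.19,
    },
    lam=None,
    normalization_bounds=None,
    provenance="published_reference",
)


@dataclass
class CVResult:
    """Cross-validation path: per-lambda mean error, its SE, and the pick.

    ``alphas`` is descending; ``coef_path`` holds the full-data coefficient
    path (features x lambdas), useful for inspecting the least-penalized fit.
    """

    alphas: np.ndarray
    mean_cv_error: np.ndarray
    se_cv_error: np.ndarray
    alpha_min: float
    alpha_1se: float
    coef_path: pd.DataFrame
    intercept_path: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lambda": self.alphas,
                "mean_cv_error": self.mean_cv_error,
                "se_cv_error": self.se_cv_error,
                "n_nonzero": (self.coef_path.to_numpy() != 0).sum(axis=0),
            }
        )

    @property
    def densest_coefficients(self) -> pd.Series:
        """Coefficients at the smallest (least-regularizing) grid lambda."""
        return self.coef_path.iloc[:, -1]


def _lambda_grid(
    X: np.ndarray, y: np.ndarray, n_lambdas: int, min_ratio: float
) -> np.ndarray:
    n = len(y)
    alpha_max = np.abs(X.T @ (y - y.mean())).max() / n
    if alpha_max <= 0:
        alpha_max = 1e-3  # degenerate response; grid is irrelevant
    return np.geomspace(alpha_max, alpha_max * min_ratio, n_lambdas)


def _centered_path(X: np.ndarray, y: np.ndarray, alphas: np.ndarray):
    """Lasso path with an (implicit) intercept via centering."""
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    _, coefs, _ = lasso_path(X - x_mean, y - y_mean, alphas=alphas, **_LASSO_KW)
    intercepts = y_mean - x_mean @ coefs
    return coefs, intercepts  # shapes (p, L), (L,)


def fit_lasso_cv(
    matrix: ModelMatrix,
    folds: int = 10,
    seed: int | None = None,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-4,
) -> tuple[ElutionModelSpec, CVResult]:
    """L1-penalized fit over a log-spaced lambda grid, one-SE selection.

    The grid runs from lambda_max (the smallest penalty giving the all-zero
    model) down by ``lambda_min_ratio``; tenfold CV assigns rows to folds
    uniformly at random given *seed*; the selected lambda is the largest one
    whose mean CV error is within one standard error of the minimum.
    Zero-coefficient features are absent from the returned spec.
    """
    X = matrix.X.to_numpy(dtype=float)
    y = matrix.y.to_numpy(dtype=float)
    names = list(matrix.X.columns)
    if len(y) < folds:
        raise ValueError(f"need at least {folds} rows for {folds}-fold CV")

    if np.ptp(y) == 0:
        warnings.warn("constant response: returning intercept-only model")
        spec = ElutionModelSpec(
            intercept=float(y.mean()), coefficients={}, lam=0.0,
            normalization_bounds=matrix.bounds,
        )
        empty = CVResult(
            alphas=np.array([0.0]), mean_cv_error=np.array([0.0]),
            se_cv_error=np.array([0.0]), alpha_min=0.0, alpha_1se=0.0,
            coef_path=pd.DataFrame(np.zeros((len(names), 1)), index=names),
            intercept_path=np.array([float(y.mean())]),
        )
        return spec, empty

    alphas = _lambda_grid(X, y, n_lambdas, lambda_min_ratio)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_mse = np.empty((folds, len(alphas)))
    for k, (tr, va) in enumerate(kf.split(X)):
        coefs, intercepts = _centered_path(X[tr], y[tr], alphas)
        pred = X[va] @ coefs + intercepts  # (n_va, L)
        fold_mse[k] = ((pred - y[va, None]) ** 2).mean(axis=0)
    mean_cv = fold_mse.mean(axis=0)
    se_cv = fold_mse.std(axis=0, ddof=1) / np.sqrt(folds)

    i_min = int(np.argmin(mean_cv))
    threshold = mean_cv[i_min] + se_cv[i_min]
    i_1se = int(np.nonzero(mean_cv <= threshold)[0][0])  # alphas descending

    coefs_full, intercepts_full = _centered_path(X, y, alphas)
    coef_path = pd.DataFrame(coefs_full, index=names)
    chosen = coef_path.iloc[:, i_1se]
    spec = ElutionModelSpec(
        intercept=float(intercepts_full[i_1se]),
        coefficients={n: float(c) for n, c in chosen.items() if c != 0.0},
        lam=float(alphas[i_1se]),
        normalization_bounds=matrix.bounds,
    )
    cv = CVResult(
        alphas=alphas, mean_cv_error=mean_cv, se_cv_error=se_cv,
        alpha_min=float(alphas[i_min]), alpha_1se=float(alphas[i_1se]),
        coef_path=coef_path, intercept_path=intercepts_full,
    )
    return spec, cv


def _fit_at_lambda(X: pd.DataFrame, y: np.ndarray, alpha: float):
    model = Lasso(alpha=alpha, fit_intercept=True, **_LASSO_KW)
    model.fit(X.to_numpy(dtype=float), y)
    return float(model.intercept_), dict(zip(X.columns, model.coef_))


def _cv_mse_at_lambda(
    X: pd.DataFrame, y: np.ndarray, alpha: float, folds: int, seed: int | None
) -> tuple[float, float]:
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    Xv = X.to_numpy(dtype=float)
    mses = []
    for tr, va in kf.split(Xv):
        model = Lasso(alpha=alpha, fit_intercept=True, **_LASSO_KW)
        model.fit(Xv[tr], y[tr])
        mses.append(float(((model.predict(Xv[va]) - y[va]) ** 2).mean()))
    mses = np.asarray(mses)
    return float(mses.mean()), float(mses.std(ddof=1) / np.sqrt(folds))


def prune_minimal_features(
    spec: ElutionModelSpec,
    matrix: ModelMatrix,
    threshold: float = 0.5,
    folds: int = 10,
    seed: int | None = None,
    cv_guard: bool = True,
) -> ElutionModelSpec:
    """Drop minimally contributing features and refit at the same lambda.

    A feature is a pruning candidate when |coefficient| < *threshold*
    (isopropanol % per normalized unit). With ``cv_guard`` (default), a
    candidate is only dropped if refitting without it does not worsen the
    CV error by more than one standard error of the current model's CV
    error. Dropping and refitting iterate until stable.
    """
    if spec.lam is None:
        raise ValueError("spec carries no lambda; prune applies to trained models")
    y = matrix.y.to_numpy(dtype=float)
    feats = list(spec.coefficients)
    coefs = dict(spec.coefficients)
    intercept = spec.intercept

    for _ in range(len(FEATURE_NAMES) + 1):
        candidates = sorted(
            (f for f in feats if abs(coefs[f]) < threshold),
            key=lambda f: abs(coefs[f]),
        )
        if cv_guard and candidates:
            base_mean, base_se = _cv_mse_at_lambda(
                matrix.X[feats], y, spec.lam, folds, seed
            )
            allowed = []
            for f in candidates:
                rest = [g for g in feats if g != f]
                if not rest:
                    allowed.append(f)
                    continue
                mean_wo, _ = _cv_mse_at_lambda(matrix.X[rest], y, spec.lam, folds, seed)
                if mean_wo <= base_mean + base_se:
                    allowed.append(f)
                else:
                    log.info("pruning kept %r: removal worsens CV error", f)
            candidates = allowed
        if not candidates:
            break
        feats = [f for f in feats if f not in candidates]
        if not feats:
            warnings.warn("pruning removed all features: intercept-only model")
            return replace(spec, coefficients={}, intercept=float(y.mean()))
        intercept, fitted = _fit_at_lambda(matrix.X[feats], y, spec.lam)
        coefs = {f: float(c) for f, c in fitted.items() if c != 0.0}
        if set(coefs) == set(feats) and all(abs(c) >= threshold for c in coefs.values()):
            feats = list(coefs)
            break
        feats = list(coefs)

    return replace(spec, coefficients=coefs, intercept=float(intercept))


# ---------------------------------------------------------------------------
# prediction & evaluation
# ---------------------------------------------------------------------------

def predict(
    spec: ElutionModelSpec,
    features: pd.DataFrame | pd.Series,
    normalized: bool = False,
) -> np.ndarray | float:
    """Predicted isopropanol elution concentration(s), unclamped.

    *features* holds raw feature values (a row per peptide, or a single
    Series); set ``normalized=True`` if they are already Max-Min normalized.
    """
    single = isinstance(features, pd.Series)
    frame = features.to_frame().T if single else features

    needed = spec.feature_names
    missing = [f for f in needed if f not in frame.columns]
    if missing:
        raise ValueError(f"missing required features: {missing}")
    if not needed:  # intercept-only model: no normalization required
        out = np.full(len(frame), spec.intercept)
        return float(out[0]) if single else out
    if not normalized:
        if spec.normalization_bounds is None:
            raise ValueError(
                "model spec carries no normalization bounds; attach them with "
                "with_bounds() or pass normalized features"
            )
        missing_bounds = [
            f for f in needed if f not in spec.normalization_bounds.index
        ]
        if missing_bounds:
            raise ValueError(f"missing normalization bounds for: {missing_bounds}")
        frame, _ = min_max_normalize(frame[needed], spec.normalization_bounds)
    else:
        frame = frame[needed]

    w = np.array([spec.coefficients[f] for f in needed], dtype=float)
    out = spec.intercept + frame.to_numpy(dtype=float) @ w
    return float(out[0]) if single else out


def snap_to_fractions(
    values: np.ndarray | float, fractions=ELUTION_CONCENTRATIONS
) -> np.ndarray | float:
    """Nearest elution concentration in {90, 85, 80, 75, 70} (ties upward)."""
    arr = np.atleast_1d(np.asarray(values, dtype=float))
    grid = np.asarray(fractions, dtype=float)  # descending: ties pick higher
    snapped = grid[np.abs(arr[:, None] - grid[None, :]).argmin(axis=1)]
    return float(snapped[0]) if np.isscalar(values) or np.ndim(values) == 0 else snapped


@dataclass
class AccuracyReport:
    """Per-fraction and overall prediction accuracy, RMSE and R^2.

    A prediction counts as correct when it falls within ``tolerance``
    percentage points of the observed elution concentration. ``accuracy``
    (the headline number) is the mean of the per-fraction accuracies over
    non-empty fractions; ``pooled_accuracy`` weights every test peptide
    equally instead.
    """

    per_fraction: dict  # observed conc -> accuracy % (NaN if empty)
    accuracy: float
    pooled_accuracy: float
    rmse: float
    r2: float
    tolerance: float
    n: int

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"fraction": conc, "accuracy_percent": acc}
            for conc, acc in sorted(self.per_fraction.items(), reverse=True)
        ]
        rows.append({"fraction": "mean", "accuracy_percent": self.accuracy})
        return pd.DataFrame(rows)


def evaluate(
    spec: ElutionModelSpec,
    features: pd.DataFrame,
    observed: pd.Series,
    tolerance: float = 5.0,
    normalized: bool = False,
) -> AccuracyReport:
    """Score predictions against observed elution concentrations."""
    if len(observed) == 0:
        raise ValueError("empty test set")
    pred = np.asarray(predict(spec, features, normalized=normalized), dtype=float)
    obs = observed.to_numpy(dtype=float)
    resid = pred - obs
    within = np.abs(resid) <= tolerance

    per_fraction: dict = {}
    for conc in sorted(np.unique(obs), reverse=True):
        mask = obs == conc
        per_fraction[float(conc)] = 100.0 * float(within[mask].mean())
    accs = [a for a in per_fraction.values() if not np.isnan(a)]

    ss_res = float((resid**2).sum())
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return AccuracyReport(
        per_fraction=per_fraction,
        accuracy=float(np.mean(accs)),
        pooled_accuracy=100.0 * float(within.mean()),
        rmse=float(np.sqrt((resid**2).mean())),
        r2=r2,
        tolerance=tolerance,
        n=len(obs),
    )
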