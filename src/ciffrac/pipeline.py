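"""End-to-end orchestration: tables -> matrix -> model -> report.

Thin glue over the stage modules so the CLI, the analysis drivers, and the
acceptance checks all execute the identical path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import model as model_mod
from . import preprocess, synthetic
from .features import featurize_many
from .model import AccuracyReport, CVResult, ElutionModelSpec
from .preprocess import ModelMatrix


def derive_seeds(seed: int | None, n: int) -> list:
    """Fan one user seed out to *n* independent integer sub-seeds (< 2^31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def build_matrix_from_lfq(lfq: pd.DataFrame, pH: float = 7.0) -> ModelMatrix:
    """LFQ table -> normalized model matrix with observed elution labels.

    Labels come from the max-LFQ-intensity rule (0%-max and all-zero rows
    removed); features are computed per retained sequence and Max-Min
    normalized over the full matrix before any split.
    """
    observed = preprocess.assign_elution_concentration(lfq)
    raw = featurize_many(list(observed.index), pH=pH)
    return preprocess.build_model_matrix(raw, observed)


@dataclass
class TrainResult:
    spec: ElutionModelSpec
    cv: CVResult
    report_test: AccuracyReport
    report_train: AccuracyReport
    train_index: np.ndarray
    test_index: np.ndarray


def train_and_evaluate(
    matrix: ModelMatrix,
    seed: int | None = None,
    folds: int = 10,
    train_fraction: float = 2.0 / 3.0,
    prune_threshold: float = 0.5,
    tolerance: float = 5.0,
    prune: bool = True,
    cv_guard: bool = True,
) -> TrainResult:
    """Split 2/3-1/3, fit the one-SE Lasso on train, prune, score both halves."""
    split_seed, cv_seed = derive_seeds(seed, 2)
    train_idx, test_idx = preprocess.train_test_split(
        matrix.X.index, train_fraction=train_fraction, seed=split_seed
    )
    train = ModelMatrix(
        X=matrix.X.loc[train_idx], y=matrix.y.loc[train_idx], bounds=matrix.bounds
    )
    spec, cv = model_mod.fit_lasso_cv(train, folds=folds, seed=cv_seed)
    if prune and spec.coefficients:
        spec = model_mod.prune_minimal_features(
            spec, train, threshold=prune_threshold, folds=folds, seed=cv_seed,
            cv_guard=cv_guard,
        )
    report_test = model_mod.evaluate(
        spec, matrix.X.loc[test_idx], matrix.y.loc[test_idx],
        tolerance=tolerance, normalized=True,
    )
    report_train = model_mod.evaluate(
        spec, matrix.X.loc[train_idx], matrix.y.loc[train_idx],
        tolerance=tolerance, normalized=True,
    )
    return TrainResult(spec, cv, report_test, report_train, train_idx, test_idx)


def run_synthetic_study(
    target_n_peptides: int = 5000,
    seed: int | None = None,
    carryover: float = 0.2,
    noise_sd: float = 3.82,
    folds: int = 10,
    tolerance: float = 5.0,
    prune: bool = True,
    **sample_kwargs,
) -> dict:
    """Simulate a study set and run the full modeling pipeline on it.

    Returns the sample set, the model matrix, the train result, and the
    label-recovery rate of the LFQ argmax assignment against ground truth.
    """
    sim_seed, fit_seed = derive_seeds(seed, 2)
    sample = synthetic.generate_sample_set(
        target_n_peptides=target_n_peptides, seed=sim_seed,
        carryover=carryover, noise_sd=noise_sd, **sample_kwargs,
    )
    matrix = build_matrix_from_lfq(sample.lfq)
    observed = preprocess.assign_elution_concentration(sample.lfq)
    truth = sample.observations["observed_conc"].loc[observed.index]
    recovery = float((observed.to_numpy() == truth.to_numpy()).mean())
    result = train_and_evaluate(
        matrix, seed=fit_seed, folds=folds, tolerance=tolerance, prune=prune
    )
    return {
        "sample": sample,
        "matrix": matrix,
        "train_result": result,
        "label_recovery": recovery,
    }
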