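"""From fraction-wise LFQ intensities to a normalized model matrix.

The elution label of a peptide is the isopropanol concentration of the
fraction in which it shows its maximum LFQ intensity across all replicates
and concentrations. Peptides whose maximum falls in the 0% fraction carry
no usable elution information (they eluted outside the stepped gradient)
and are removed, as are peptides never observed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Stepwise isopropanol elution concentrations (%), plus the 0% wash.
ELUTION_CONCENTRATIONS = (90, 85, 80, 75, 70)
ALL_CONCENTRATIONS = ELUTION_CONCENTRATIONS + (0,)


def make_lfq_columns(
    concentrations: Sequence[int] = ALL_CONCENTRATIONS, replicates: int = 3
) -> pd.MultiIndex:
    """Column index for an LFQ table: (isopropanol %, replicate id)."""
    return pd.MultiIndex.from_product(
        [list(concentrations), range(1, replicates + 1)],
        names=["isopropanol_percent", "replicate"],
    )


def _validate_lfq(table: pd.DataFrame) -> pd.DataFrame:
    if table.empty:
        raise ValueError("LFQ table is empty")
    if table.columns.nlevels != 2:
        raise ValueError(
            "LFQ table columns must be a (isopropanol_percent, replicate) "
            f"MultiIndex; got {table.columns!r}"
        )
    for conc, rep in table.columns:
        if not (isinstance(conc, (int, np.integer)) and int(conc) in ALL_CONCENTRATIONS):
            raise ValueError(
                f"malformed LFQ column ({conc!r}, {rep!r}): concentration must "
                f"be one of {ALL_CONCENTRATIONS}"
            )
    if (table.to_numpy() < 0).any():
        raise ValueError("LFQ intensities must be non-negative")
    return table


def assign_elution_concentration(table: pd.DataFrame) -> pd.Series:
    """Observed elution concentration per retained peptide.

    Parameters
    ----------
    table
        Rows indexed by peptide sequence; columns (isopropanol %, replicate);
        missing intensities as 0.

    Returns
    -------
    Series mapping sequence -> observed isopropanol % in {90,85,80,75,70}.
    Peptides with an all-zero row or with the global maximum in the 0%
    fraction are dropped. Argmax ties break toward the highest isopropanol
    concentration, then the lowest replicate id.
    """
    _validate_lfq(table)
    # Order columns so that np.argmax's first-maximum rule implements the
    # tie-break: highest concentration first, then lowest replicate.
    ordered = table.sort_index(
        axis=1, level=["isopropanol_percent", "replicate"], ascending=[False, True]
    )
    values = ordered.to_numpy(dtype=float)
    best = values.argmax(axis=1)
    concs = ordered.columns.get_level_values("isopropanol_percent").to_numpy()[best]
    observed = pd.Series(concs, index=table.index, name="observed_conc")

    nonzero = values.max(axis=1) > 0
    retained = nonzero & (observed.to_numpy() != 0)
    n_zero_max = int((nonzero & (observed.to_numpy() == 0)).sum())
    if n_zero_max:
        log.info("removed %d peptides eluting maximally at 0%% isopropanol", n_zero_max)
    if (~nonzero).any():
        log.info("removed %d peptides with all-zero intensities", int((~nonzero).sum()))
    return observed[retained].astype(int)


@dataclass
class ModelMatrix:
    """Normalized feature matrix with its response and normalization bounds.

    ``bounds`` stores per-column (min, max) of the raw features so that the
    same affine map can be replayed on new peptides at prediction time.
    """

    X: pd.DataFrame  # normalized to [0, 1]
    y: pd.Series  # observed isopropanol %
    bounds: pd.DataFrame  # index = feature names, columns = ["min", "max"]

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.y.index):
            raise ValueError("X and y must share an index")


def min_max_normalize(
    raw: pd.DataFrame, bounds: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Max-Min normalize each column to [0, 1]; return (normalized, bounds).

    With *bounds* given, replays stored (min, max) instead of refitting
    (values outside the stored range then fall outside [0, 1]).
    Constant columns map to 0 with a logged warning.
    """
    if bounds is None:
        if len(raw) < 2:
            raise ValueError("need at least 2 rows to fit normalization bounds")
        bounds = pd.DataFrame(
            {"min": raw.min(axis=0), "max": raw.max(axis=0)}, index=raw.columns
        )
    missing = [c for c in raw.columns if c not in bounds.index]
    if missing:
        raise ValueError(f"no normalization bounds for columns: {missing}")
    lo = bounds["min"].reindex(raw.columns)
    span = bounds["max"].reindex(raw.columns) - lo
    constant = span == 0
    if constant.any():
        log.warning(
            "constant feature column(s) %s normalized to 0",
            list(raw.columns[constant.to_numpy()]),
        )
    safe_span = span.replace(0, 1.0)
    normalized = (raw - lo) / safe_span
    normalized.loc[:, constant.to_numpy()] = 0.0
    return normalized, bounds


def denormalize(normalized: pd.DataFrame, bounds: pd.DataFrame) -> pd.DataFrame:
    """Invert :func:`min_max_normalize` using stored bounds."""
    lo = bounds["min"].reindex(normalized.columns)
    span = bounds["max"].reindex(normalized.columns) - lo
    return normalized * span + lo


def build_model_matrix(
    raw_features: pd.DataFrame, observed: pd.Series
) -> ModelMatrix:
    """Align features with elution labels and normalize the full matrix.

    Bounds are fit on the complete matrix before any train/test split; pass
    the split indices through :func:`train_test_split` afterwards (strict
    train-only bounds are available by normalizing the train slice directly).
    """
    common = raw_features.index.intersection(observed.index)
    X_raw = raw_features.loc[common]
    y = observed.loc[common].astype(float)
    X, bounds = min_max_normalize(X_raw)
    return ModelMatrix(X=X, y=y, bounds=bounds)


def train_test_split(
    index: Sequence, train_fraction: float = 2.0 / 3.0, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint, exhaustive partition of *index* into (train, test).

    The train set holds round(train_fraction * n) elements (round half up),
    so a 39,225-row matrix at a one-third test fraction leaves exactly
    13,075 test rows.
    """
    items = np.asarray(index)
    n = len(items)
    if n < 3:
        raise ValueError(f"need at least 3 rows to split, got {n}")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n_train = int(np.floor(train_fraction * n + 0.5))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return items[np.sort(perm[:n_train])], items[np.sort(perm[n_train:])]
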