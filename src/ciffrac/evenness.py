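"""Distribution index: evenness of PSM elution across an LC gradient.

The gradient (default 70 min) is partitioned into equal bins (default 70,
i.e. 1-min bins) and the peptide-spectral-match count in bin j is P_j. Each
bin is capped at the flat-histogram height (total / n_bins); the index is
the capped total as a percentage of the total:

    index = 100 * sum_j min(P_j, total / n_bins) / total

Geometrically this is the overlap between the observed histogram and a flat
histogram of equal area: 100% for a perfectly even distribution, down to
100 / n_bins when every PSM falls in a single bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class RetentionHistogram:
    """Binned PSM counts over a gradient; bins are [j-1, j) minutes (last closed)."""

    counts: np.ndarray
    gradient_length: float = 70.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or len(self.counts) == 0:
            raise ValueError("counts must be a non-empty 1-D array")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.gradient_length <= 0:
            raise ValueError(f"gradient_length must be positive, got {self.gradient_length}")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def bin_retention_times(
    rts, gradient_length: float = 70.0, n_bins: int = 70
) -> RetentionHistogram:
    """Histogram retention times (minutes) into equal bins over the gradient.

    Retention times outside [0, gradient_length] are clipped into the
    terminal bins (with a logged count) rather than dropped.
    """
    if gradient_length <= 0:
        raise ValueError(f"gradient_length must be positive, got {gradient_length}")
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        raise ValueError("no retention times given")
    out_of_range = int(((rts < 0) | (rts > gradient_length)).sum())
    if out_of_range:
        log.warning(
            "%d retention times outside [0, %.4g] min clipped into terminal bins",
            out_of_range, gradient_length,
        )
    clipped = np.clip(rts, 0.0, gradient_length)
    counts, _ = np.histogram(clipped, bins=n_bins, range=(0.0, gradient_length))
    return RetentionHistogram(counts=counts.astype(float), gradient_length=gradient_length)


def distribution_index(hist: RetentionHistogram) -> float:
    """Percentage overlap of the observed histogram with the flat histogram.

    Raises ``ValueError`` on an all-zero histogram (the index is undefined
    without any PSM).
    """
    total = hist.total
    if total <= 0:
        raise ValueError("distribution index undefined for an all-zero histogram")
    cap = total / hist.n_bins
    return 100.0 * float(np.minimum(hist.counts, cap).sum()) / total


def per_fraction_distribution_index(
    evidence: pd.DataFrame,
    rt_column: str = "Retention time",
    fraction_column: str = "Raw file",
    gradient_length: float = 70.0,
    n_bins: int = 70,
) -> pd.DataFrame:
    """One distribution index per fraction of an evidence-style PSM table.

    Returns a frame with columns ``fraction``, ``n_psms``,
    ``distribution_index_percent``, one row per distinct value of
    *fraction_column*.
    """
    for col in (rt_column, fraction_column):
        if col not in evidence.columns:
            raise ValueError(f"evidence table lacks required column {col!r}")
    rows = []
    for fraction, group in evidence.groupby(fraction_column, sort=True):
        hist = bin_retention_times(
            group[rt_column].to_numpy(), gradient_length, n_bins
        )
        rows.append(
            {
                "fraction": fraction,
                "n_psms": int(hist.total),
                "distribution_index_percent": distribution_index(hist),
            }
        )
    return pd.DataFrame(rows)
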