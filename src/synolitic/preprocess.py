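"""Feature robustness filtering, fold-safe standardization, MI selection.

All fitting here is fold-safe by construction: :func:`zscore_fit` and
:func:`mi_rank` take an explicit set of training rows and never look at
anything else, and both report the rows they consumed to the leakage
instrumentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.feature_selection import mutual_info_classif

from ._rng import subseed
from .cohort import FeatureTable
from .errors import ConfigurationError, StructuralError
from .instrument import record_fit_rows

__all__ = [
    "StandardizationParams",
    "FeatureRanking",
    "icc_filter",
    "compute_icc",
    "zscore_fit",
    "zscore_apply",
    "zscore_invert",
    "mi_rank",
    "select_top_n",
]


@dataclass(frozen=True)
class StandardizationParams:
    """Per-feature mean and sample SD (ddof=1), estimated on a training fold."""

    feature_names: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray


@dataclass(frozen=True)
class FeatureRanking:
    """Features ordered by decreasing mutual information with the label.

    Ties are broken lexicographically by feature name so the ranking is
    deterministic across reruns.
    """

    entries: tuple[tuple[str, float], ...]

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.entries]

    @property
    def scores(self) -> list[float]:
        return [score for _, score in self.entries]

    def to_frame(self, n_selected: int | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.entries, columns=["feature", "mi_score"])
        df["rank"] = np.arange(1, len(df) + 1)
        if n_selected is not None:
            df["selected"] = df["rank"] <= n_selected
        return df


def compute_icc(measurements: np.ndarray) -> float:
    """ICC(2,1): two-way, absolute-agreement, single-measurement.

    ``measurements`` is subjects x versions.  Estimated from the classical
    variance-component decomposition of the two-way ANOVA table.
    """
    m = np.asarray(measurements, dtype=np.float64)
    n, k = m.shape
    if n < 2 or k < 2:
        raise ConfigurationError("ICC needs >= 2 subjects and >= 2 measurements")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        return 0.0
    return float((msr - mse) / denom)


def _check_aligned(original: FeatureTable, replicates: Sequence[FeatureTable]) -> None:
    for rep in replicates:
        if rep.patient_ids != original.patient_ids:
            raise StructuralError("replicate patient ids do not match original")
        if rep.feature_names != original.feature_names:
            raise StructuralError("replicate feature names do not match original")


def icc_filter(
    original: FeatureTable,
    replicates: Sequence[FeatureTable],
    cutoff: float = 0.8,
) -> list[str]:
    """Retain features whose ICC across measurement versions is > ``cutoff``.

    The inequality is strict: a feature at exactly the cutoff is dropped.
    Input column order is preserved; replicate order is immaterial (the ICC
    is symmetric in measurement versions).
    """
    if len(replicates) < 1:
        raise ConfigurationError("need at least one replicate (>= 2 measurements)")
    _check_aligned(original, replicates)
    stacks = np.stack([original.values] + [r.values for r in replicates], axis=2)
    retained = []
    for j, name in enumerate(original.feature_names):
        if compute_icc(stacks[:, j, :]) > cutoff:
            retained.append(name)
    return retained


def zscore_fit(table: FeatureTable, rows: Sequence[int]) -> StandardizationParams:
    """Estimate per-feature mean/SD on the given training rows only."""
    rows = np.asarray(rows, dtype=int)
    record_fit_rows("zscore_fit", (table.patient_ids[i] for i in rows))
    x = table.values[rows]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        names = [table.feature_names[j] for j in constant]
        raise ConfigurationError(f"constant training columns: {names}")
    return StandardizationParams(tuple(table.feature_names), mean, sd)


def zscore_apply(table: FeatureTable, params: StandardizationParams) -> FeatureTable:
    """Transform any rows with training-fold parameters (no refit)."""
    if tuple(table.feature_names) != params.feature_names:
        raise StructuralError("feature names do not match standardization params")
    out = table.copy()
    out.values = (table.values - params.mean) / params.sd
    return out


def zscore_invert(table: FeatureTable, params: StandardizationParams) -> FeatureTable:
    if tuple(table.feature_names) != params.feature_names:
        raise StructuralError("feature names do not match standardization params")
    out = table.copy()
    out.values = table.values * params.sd + params.mean
    return out


def mi_rank(
    table: FeatureTable, rows: Sequence[int], seed: int = 0, n_neighbors: int = 3
) -> FeatureRanking:
    """Rank features by estimated mutual information with the binary label.

    Uses the k-nearest-neighbour MI estimator for continuous features
    against a discrete target (k = 3 by default).  The estimator is
    randomized; it is seeded so the contract "deterministic given seed"
    holds.  Computed from training rows only.
    """
    rows = np.asarray(rows, dtype=int)
    y = table.labels[rows]
    if len(np.unique(y)) < 2:
        raise ConfigurationError("training rows contain a single class")
    record_fit_rows("mi_rank", (table.patient_ids[i] for i in rows))
    scores = mutual_info_classif(
        table.values[rows],
        y,
        n_neighbors=n_neighbors,
        random_state=subseed(seed, "mi_rank"),
    )
    order = sorted(
        range(table.n_features),
        key=lambda j: (-scores[j], table.feature_names[j]),
    )
    entries = tuple(
        (table.feature_names[j], float(max(scores[j], 0.0))) for j in order
    )
    return FeatureRanking(entries)


def select_top_n(ranking: FeatureRanking, n: int) -> list[str]:
    """First ``n`` names of the ranking (a prefix, stable across reruns)."""
    if n > len(ranking.entries):
        raise ConfigurationError(
            f"cannot select {n} features from {len(ranking.entries)}"
        )
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    return ranking.names[:n]
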