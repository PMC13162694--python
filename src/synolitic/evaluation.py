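"""Leakage-safe cross-validation harness, metrics aggregation, reporting.

Every model arm — conventional, simplified graph-summary, and end-to-end
GNN — runs under the same 5-fold stratified protocol: all fitting
(standardization, MI selection, pairwise models, hyperparameter tuning,
classifier training) happens strictly inside each training fold, and the
test fold only ever contributes feature values at scoring time.  Folds are
shared across arms for a given seed, so arm comparisons are paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.model_selection import StratifiedKFold

from ._rng import subseed
from .baselines import BaselineSpec, run_baseline, run_simplified_sgnn
from .cohort import FeatureTable
from .config import ExperimentConfig
from .errors import ConfigurationError
from .graphs import build_fold_graphs
from .instrument import record_fit_rows
from .metrics import metrics
from .nn import build_model, predict_proba, train, tune
from .preprocess import zscore_apply, zscore_fit

__all__ = [
    "FoldAssignment",
    "EvalResult",
    "stratified_kfold",
    "run_cv_experiment",
    "cohort_summary",
    "report",
    "metrics",
]

GNN_ARMS = ("gcn", "gatv2")
BASELINE_ARMS = {
    "gb": "gradient_boosting",
    "rf": "random_forest",
    "svm": "svm_rbf",
    "lr": "logistic_regression",
}
SIMPLIFIED_ARMS = {"sgnn_gb": "gradient_boosting", "sgnn_rf": "random_forest"}


@dataclass(frozen=True)
class FoldAssignment:
    """Stratified partition: per-patient fold index."""

    fold_index: np.ndarray
    k: int
    seed: int

    def split(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = np.flatnonzero(self.fold_index == fold)
        train = np.flatnonzero(self.fold_index != fold)
        return train, test


def stratified_kfold(labels: Sequence[int], k: int = 5, seed: int = 0) -> FoldAssignment:
    """Deterministic stratified k-fold; per-fold class counts within one
    patient of the global prevalence."""
    y = np.asarray(labels, dtype=int)
    if np.bincount(y, minlength=2).min() < k:
        raise ConfigurationError(f"each class needs at least {k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True,
                          random_state=subseed(seed, "folds"))
    fold_index = np.empty(len(y), dtype=int)
    for f, (_, test) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        fold_index[test] = f
    return FoldAssignment(fold_index=fold_index, k=k, seed=seed)


@dataclass
class EvalResult:
    """Per-fold and aggregate ROC-AUC / F1 / accuracy for one arm."""

    experiment_id: str
    fold_metrics: pd.DataFrame  # columns: fold, auc, f1, accuracy
    selected_features: list[list[str]] = field(default_factory=list)
    config_fingerprint: str = ""

    def aggregate(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for m in ("auc", "f1", "accuracy"):
            vals = self.fold_metrics[m].to_numpy()
            out[f"{m}_mean"] = float(vals.mean())
            out[f"{m}_sd"] = float(vals.std(ddof=1))
        return out

    def summary_row(self) -> dict:
        row = {"experiment_id": self.experiment_id}
        row.update(self.aggregate())
        return row


def _run_gnn_arm(config, train_graphs, test_graphs, fold_seed):
    node_dim = train_graphs[0].node_features.shape[1]
    labels = np.array([g.label for g in train_graphs], dtype=int)
    gnn_cfg = config.gnn.with_seed(fold_seed)
    if config.search is not None and config.search.n_trials > 1:
        budget = replace(config.search, sampler_seed=fold_seed)
        _, model, _ = tune(train_graphs, labels, gnn_cfg, budget, node_dim)
    else:
        model = build_model(gnn_cfg, node_dim)
        train(model, train_graphs, labels, gnn_cfg)
    return predict_proba(model, test_graphs)


def run_cv_experiment(table: FeatureTable, config: ExperimentConfig) -> EvalResult:
    """Run one arm of the benchmark grid under shared stratified folds."""
    config.validate()
    table.validate(require_both_classes=True)
    folds = stratified_kfold(table.labels, k=config.k_folds, seed=config.seed)
    rows, selected_per_fold = [], []
    for f in range(config.k_folds):
        tr_idx, te_idx = folds.split(f)
        tr_tab, te_tab = table.subset_rows(tr_idx), table.subset_rows(te_idx)
        record_fit_rows(f"fold_boundary:{f}", [])
        fold_seed = subseed(config.seed, f"fold{f}")
        if config.arm in BASELINE_ARMS:
            params = zscore_fit(tr_tab, np.arange(tr_tab.n_patients))
            probs = run_baseline(
                zscore_apply(tr_tab, params),
                zscore_apply(te_tab, params),
                BaselineSpec(model=BASELINE_ARMS[config.arm], seed=fold_seed),
            )
            selected_per_fold.append(list(table.feature_names))
        else:
            tr_graphs, te_graphs, info = build_fold_graphs(
                tr_tab,
                te_tab,
                n_selected=config.n_selected,
                sparsifier=config.sparsifier,
                use_topology=config.node_topology,
                seed=fold_seed,
            )
            selected_per_fold.append(info["selected"])
            if config.arm in SIMPLIFIED_ARMS:
                probs = run_simplified_sgnn(
                    tr_graphs,
                    tr_tab.labels,
                    te_graphs,
                    model=SIMPLIFIED_ARMS[config.arm],
                    seed=fold_seed,
                )
            elif config.arm in GNN_ARMS:
                probs = _run_gnn_arm(config, tr_graphs, te_graphs, fold_seed)
            else:
                raise ConfigurationError(f"unknown arm {config.arm!r}")
        row = {"fold": f}
        row.update(metrics(probs, te_tab.labels))
        rows.append(row)
    return EvalResult(
        experiment_id=config.experiment_id(),
        fold_metrics=pd.DataFrame(rows),
        selected_features=selected_per_fold,
        config_fingerprint=config.fingerprint(),
    )


def cohort_summary(table: FeatureTable, columns: Sequence[str]) -> pd.DataFrame:
    """Per-column median (IQR) by class with two-sided Mann–Whitney U tests.

    Exact null distribution for small groups without ties (both classes
    <= 20), otherwise the normal approximation with continuity and tie
    correction.
    """
    table.validate(require_both_classes=True)
    index = {f: j for j, f in enumerate(table.feature_names)}
    pos = table.labels == 1
    rows = []
    for name in columns:
        if name not in index:
            raise ConfigurationError(f"unknown column {name!r}")
        v = table.values[:, index[name]]
        a, b = v[pos], v[~pos]
        has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = "exact" if (max(len(a), len(b)) <= 20 and not has_ties) else "asymptotic"
        res = mannwhitneyu(a, b, alternative="two-sided", method=method)
        q = lambda x: np.percentile(x, (25, 50, 75))
        qa, qb = q(a), q(b)
        rows.append(
            {
                "feature": name,
                "positive_median": qa[1],
                "positive_iqr": f"{qa[0]:.3g}-{qa[2]:.3g}",
                "negative_median": qb[1],
                "negative_iqr": f"{qb[0]:.3g}-{qb[2]:.3g}",
                "u_statistic": float(res.statistic),
                "p_value": float(res.pvalue),
            }
        )
    return pd.DataFrame(rows)


def report(results: Sequence[EvalResult], out_dir=None) -> pd.DataFrame:
    """Ranked comparison table (mean AUC descending, ties by name); if
    ``out_dir`` is given, writes CSV and a bar chart with SD whiskers."""
    if not results:
        raise ConfigurationError("no results to report")
    df = pd.DataFrame([r.summary_row() for r in results])
    df = df.sort_values(
        ["auc_mean", "experiment_id"], ascending=[False, True]
    ).reset_index(drop=True)
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "comparison.csv", index=False)
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 0.5 * len(df) + 2))
        ax.barh(df["experiment_id"], df["auc_mean"], xerr=df["auc_sd"],
                color="steelblue")
        ax.set_xlabel("ROC-AUC (mean ± SD across folds)")
        ax.invert_yaxis()
        fig.tight_layout()
        fig.savefig(out / "comparison.png", dpi=150)
        plt.close(fig)
    return df
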