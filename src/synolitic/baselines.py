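"""Conventional ML benchmarks and the simplified graph-summary pipeline.

The four benchmark models use fixed hyperparameters: Gradient Boosting
(100 estimators, max depth 6, learning rate 0.1); SVM with RBF kernel,
gamma scaling and balanced class weights; Random Forest (100 trees, max
depth 10, balanced class weights); logistic regression (L-BFGS, balanced
class weights).  The simplified pipeline replaces end-to-end graph learning
with hand-crafted graph summary statistics fed to GB or RF.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from ._rng import subseed
from .cohort import FeatureTable
from .errors import ConfigurationError
from .graphs import PatientGraph, attach_node_topology
from .instrument import record_fit_rows

__all__ = [
    "BaselineSpec",
    "run_baseline",
    "graph_summary_features",
    "run_simplified_sgnn",
    "GRAPH_SUMMARY_SCHEMA",
]

BASELINE_MODELS = ("gradient_boosting", "random_forest", "svm_rbf", "logistic_regression")


@dataclass(frozen=True)
class BaselineSpec:
    model: str = "gradient_boosting"
    seed: int = 0

    def validate(self) -> None:
        if self.model not in BASELINE_MODELS:
            raise ConfigurationError(f"unknown baseline model {self.model!r}")


def _make_estimator(spec: BaselineSpec):
    seed = subseed(spec.seed, f"baseline:{spec.model}")
    if spec.model == "gradient_boosting":
        return GradientBoostingClassifier(
            n_estimators=100, max_depth=6, learning_rate=0.1, random_state=seed
        )
    if spec.model == "random_forest":
        return RandomForestClassifier(
            n_estimators=100, max_depth=10, class_weight="balanced", random_state=seed
        )
    if spec.model == "svm_rbf":
        return SVC(kernel="rbf", gamma="scale", class_weight="balanced",
                   random_state=seed)
    return LogisticRegression(solver="lbfgs", class_weight="balanced", max_iter=1000)


def _fit_predict(
    estimator,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    spec: BaselineSpec,
) -> np.ndarray:
    estimator.fit(x_train, y_train)
    if hasattr(estimator, "predict_proba"):
        return estimator.predict_proba(x_test)[:, 1]
    # margin classifier: map the decision function through a monotone
    # (Platt) calibration fit on the training fold; ROC-AUC is unaffected
    # by any strictly monotone mapping, F1/accuracy get a usable scale
    margins_train = estimator.decision_function(x_train).reshape(-1, 1)
    platt = LogisticRegression(solver="lbfgs", max_iter=1000)
    platt.fit(margins_train, y_train)
    margins_test = estimator.decision_function(x_test).reshape(-1, 1)
    return platt.predict_proba(margins_test)[:, 1]


def run_baseline(
    train: FeatureTable, test: FeatureTable, spec: BaselineSpec
) -> np.ndarray:
    """Fit the named model on the training fold; return test positive-class
    probabilities.  Features are expected already z-scored with
    training-fold parameters."""
    spec.validate()
    train.validate(require_both_classes=True)
    record_fit_rows(f"baseline:{spec.model}", train.patient_ids)
    est = _make_estimator(spec)
    return _fit_predict(est, train.values, train.labels, test.values, spec)


def _aggregate(v: np.ndarray) -> list[float]:
    return [float(v.mean()), float(v.std(ddof=0)), float(v.max())]


#: Fixed, versioned order of the summary vector (schema v1).
GRAPH_SUMMARY_SCHEMA: tuple[str, ...] = tuple(
    [
        f"{c}_{stat}"
        for c in ("degree", "strength", "closeness", "betweenness")
        for stat in ("mean", "sd", "max")
    ]
    + ["n_edges", "density", "n_components", "largest_component"]
    + [f"weight_{s}" for s in ("mean", "sd", "min", "max", "q25", "q50", "q75")]
)


def graph_summary_features(g: PatientGraph) -> np.ndarray:
    """Schema-v1 summary vector: centrality aggregates over nodes (mean, SD,
    max of degree / strength / closeness / betweenness), global properties
    (edge count, density, components, largest component), and edge-weight
    statistics (mean, SD, min, max, quartiles).  A pure, label-blind
    function of the graph."""
    if g.node_features.shape[1] == 5:
        topo = g.node_features
    else:
        topo = attach_node_topology(g).node_features
    feats: list[float] = []
    for col in range(1, 5):  # degree, strength, closeness, betweenness
        feats.extend(_aggregate(topo[:, col]))
    n = g.n_nodes
    density = g.n_edges / (n * (n - 1) / 2) if n > 1 else 0.0
    nxg = g.to_networkx()
    comps = list(nx.connected_components(nxg))
    feats.extend([float(g.n_edges), density, float(len(comps)),
                  float(max(len(c) for c in comps))])
    w = g.edge_weight
    if w.size:
        feats.extend(
            [float(w.mean()), float(w.std(ddof=0)), float(w.min()), float(w.max())]
            + [float(np.quantile(w, q)) for q in (0.25, 0.5, 0.75)]
        )
    else:
        feats.extend([0.0] * 7)
    return np.asarray(feats, dtype=np.float64)


def run_simplified_sgnn(
    train_graphs: list[PatientGraph],
    train_labels: np.ndarray,
    test_graphs: list[PatientGraph],
    model: str = "gradient_boosting",
    seed: int = 0,
) -> np.ndarray:
    """Summary vectors -> GB or RF with the benchmark hyperparameters."""
    if model not in ("gradient_boosting", "random_forest"):
        raise ConfigurationError("simplified pipeline supports gb/rf only")
    spec = BaselineSpec(model=model, seed=seed)
    x_train = np.vstack([graph_summary_features(g) for g in train_graphs])
    x_test = np.vstack([graph_summary_features(g) for g in test_graphs])
    record_fit_rows(f"simplified_sgnn:{model}",
                    (g.patient_id for g in train_graphs))
    est = _make_estimator(spec)
    return _fit_predict(est, x_train, np.asarray(train_labels, dtype=int),
                        x_test, spec)
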