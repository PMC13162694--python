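"""Per-patient synolitic graphs.

Each patient's selected-feature vector is converted into a weighted graph:
nodes are the selected features; the edge between features i and j carries

    w_ij = 2 * |P(y = 1 | f_i, f_j) - 0.5|

where P comes from a logistic model fit on that feature pair within the
current training fold.  w_ij is the pairwise *discriminative confidence*
evaluated at this patient's two values: 0 means the pair says nothing about
this patient's class, 1 means it is certain (in either direction — which
class the pair votes for is deliberately discarded).

Graphs may then be sparsified (top-p by confidence, or thresholded to the
sparsest connected graph) and annotated with topological node features.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import networkx as nx
import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .cohort import FeatureTable
from .errors import ConfigurationError, StructuralError
from .instrument import record_fit_rows
from .preprocess import (
    mi_rank,
    select_top_n,
    zscore_apply,
    zscore_fit,
)

__all__ = [
    "PairwiseModelBank",
    "PatientGraph",
    "SparsifierConfig",
    "edge_weight",
    "fit_pairwise_bank",
    "build_patient_graph",
    "build_patient_graphs",
    "sparsify_top_p",
    "sparsify_min_connected",
    "apply_sparsifier",
    "attach_node_topology",
    "build_fold_graphs",
]

#: Node-feature layout when topology is attached.
NODE_FEATURE_NAMES = (
    "value",
    "degree_centrality",
    "strength",
    "closeness",
    "betweenness",
)


@dataclass(frozen=True)
class SparsifierConfig:
    """mode in {none, top_p, min_connected}; p required iff mode == top_p."""

    mode: str = "none"
    p: float | None = None

    def validate(self) -> None:
        if self.mode not in ("none", "top_p", "min_connected"):
            raise ConfigurationError(f"unknown sparsifier mode {self.mode!r}")
        if self.mode == "top_p":
            if self.p is None or not 0.0 < self.p <= 1.0:
                raise ConfigurationError("top_p requires p in (0, 1]")
        elif self.p is not None:
            raise ConfigurationError(f"p is only meaningful for top_p, got {self.p}")

    def tag(self) -> str:
        return f"top_p({self.p})" if self.mode == "top_p" else self.mode


@dataclass
class PairwiseModelBank:
    """One two-feature logistic model per unordered pair of selected features.

    Coefficients are stored densely so a whole cohort's edge weights can be
    evaluated with one vectorized pass.
    """

    selected: list[str]
    pair_index: np.ndarray  # (n_pairs, 2) indices into `selected`, i < j
    coef: np.ndarray  # (n_pairs, 2)
    intercept: np.ndarray  # (n_pairs,)
    train_fingerprint: str = ""

    @property
    def n_pairs(self) -> int:
        return self.pair_index.shape[0]

    def predict_proba_matrix(self, x: np.ndarray) -> np.ndarray:
        """P(y=1 | f_i, f_j) for every patient (rows) and pair (columns)."""
        xi = x[:, self.pair_index[:, 0]]
        xj = x[:, self.pair_index[:, 1]]
        z = xi * self.coef[:, 0] + xj * self.coef[:, 1] + self.intercept
        return 1.0 / (1.0 + np.exp(-z))


@dataclass
class PatientGraph:
    """A weighted graph over the selected features for one patient.

    ``edge_index`` holds undirected edges as (n_edges, 2) node-index pairs
    with u < v; ``node_features`` is (n_nodes, 1) before topology is
    attached and (n_nodes, 5) after.
    """

    patient_id: str
    nodes: list[str]
    node_values: np.ndarray  # (n_nodes,) standardized values
    edge_index: np.ndarray  # (n_edges, 2) int
    edge_weight: np.ndarray  # (n_edges,)
    node_features: np.ndarray  # (n_nodes, d)
    label: int | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[0]

    def validate(self) -> None:
        if self.edge_index.size and (
            self.edge_index.min() < 0 or self.edge_index.max() >= self.n_nodes
        ):
            raise StructuralError("edge endpoints out of range")
        if np.any(self.edge_index[:, 0] == self.edge_index[:, 1]):
            raise StructuralError("self-loops are not allowed")
        if self.edge_weight.size and (
            self.edge_weight.min() < 0 or self.edge_weight.max() > 1
        ):
            raise StructuralError("edge weights must lie in [0, 1]")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for k, name in enumerate(self.nodes):
            attrs = {"value": float(self.node_values[k])}
            if self.node_features.shape[1] == len(NODE_FEATURE_NAMES):
                attrs.update(
                    {
                        fname: float(self.node_features[k, fi])
                        for fi, fname in enumerate(NODE_FEATURE_NAMES)
                    }
                )
            g.add_node(name, **attrs)
        for (u, v), w in zip(self.edge_index, self.edge_weight):
            g.add_edge(self.nodes[u], self.nodes[v], weight=float(w))
        return g


def edge_weight(p: float | np.ndarray) -> float | np.ndarray:
    """Confidence rescaling ``w = 2|p - 0.5|``; symmetric in the vote direction."""
    p_arr = np.asarray(p, dtype=np.float64)
    if np.any(p_arr < 0) or np.any(p_arr > 1):
        raise ConfigurationError("probability outside [0, 1]")
    w = 2.0 * np.abs(p_arr - 0.5)
    return float(w) if np.isscalar(p) or p_arr.ndim == 0 else w


def _fingerprint(x: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(x).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def fit_pairwise_bank(train: FeatureTable, selected: Sequence[str]) -> PairwiseModelBank:
    """Fit one logistic model per unordered pair of selected features.

    Models are plain logistic regressions (L-BFGS, max 1000 iterations, L2
    with C = 1.0, no class weighting) on the standardized training fold.
    Non-convergence is logged as a warning and the last iterate kept.
    """
    selected = list(selected)
    if len(selected) < 2:
        raise ConfigurationError("need at least 2 selected features")
    train.validate(require_both_classes=True)
    record_fit_rows("pairwise_bank", train.patient_ids)
    sub = train.subset_columns(selected)
    x, y = sub.values, sub.labels
    n = len(selected)
    pairs = np.array([(i, j) for i in range(n) for j in range(i + 1, n)], dtype=int)
    coef = np.empty((len(pairs), 2))
    intercept = np.empty(len(pairs))
    with warnings.catch_warnings():
        warnings.simplefilter("always", ConvergenceWarning)
        for k, (i, j) in enumerate(pairs):
            model = LogisticRegression(
                solver="lbfgs", max_iter=1000, C=1.0, class_weight=None
            )
            model.fit(x[:, (i, j)], y)
            coef[k] = model.coef_[0]
            intercept[k] = model.intercept_[0]
    return PairwiseModelBank(
        selected=selected,
        pair_index=pairs,
        coef=coef,
        intercept=intercept,
        train_fingerprint=_fingerprint(x, y),
    )


def _graph_from_weights(
    bank: PairwiseModelBank,
    patient_id: str,
    values: np.ndarray,
    weights: np.ndarray,
    label: int | None,
) -> PatientGraph:
    g = PatientGraph(
        patient_id=patient_id,
        nodes=list(bank.selected),
        node_values=values.copy(),
        edge_index=bank.pair_index.copy(),
        edge_weight=weights,
        node_features=values.reshape(-1, 1).copy(),
        label=label,
    )
    g.validate()
    return g


def build_patient_graph(
    bank: PairwiseModelBank, patient_row: np.ndarray, patient_id: str = "patient"
) -> PatientGraph:
    """Complete graph for one (standardized) patient vector.

    Never touches any label; works identically for training and held-out
    patients.
    """
    row = np.asarray(patient_row, dtype=np.float64)
    if row.shape != (len(bank.selected),):
        raise StructuralError(
            f"expected {len(bank.selected)} feature values, got shape {row.shape}"
        )
    p = bank.predict_proba_matrix(row.reshape(1, -1))[0]
    return _graph_from_weights(bank, patient_id, row, edge_weight(p), None)


def build_patient_graphs(
    bank: PairwiseModelBank,
    table: FeatureTable,
    attach_labels: bool = False,
) -> list[PatientGraph]:
    """Vectorized graph construction for a whole (standardized) table."""
    sub = table.subset_columns(bank.selected)
    probs = bank.predict_proba_matrix(sub.values)
    weights = edge_weight(probs)
    return [
        _graph_from_weights(
            bank,
            sub.patient_ids[i],
            sub.values[i],
            weights[i],
            int(sub.labels[i]) if attach_labels else None,
        )
        for i in range(sub.n_patients)
    ]


def _edge_sort_key(g: PatientGraph) -> np.ndarray:
    """Order edges by descending weight, ties lexicographic by endpoint names."""
    names = np.array(g.nodes)
    u_names = names[g.edge_index[:, 0]]
    v_names = names[g.edge_index[:, 1]]
    swap = u_names > v_names
    lo = np.where(swap, v_names, u_names)
    hi = np.where(swap, u_names, v_names)
    return np.lexsort((hi, lo, -g.edge_weight))


def sparsify_top_p(g: PatientGraph, p: float) -> PatientGraph:
    """Keep the ``ceil(p * N(N-1)/2)`` highest-confidence edges.

    The budget is a fraction of the complete graph on the node set (the
    pipeline always sparsifies complete graphs, where this equals the
    current edge count); the ceiling guarantees at least one edge for any
    p > 0.  Node set is unchanged; isolated nodes are permitted.
    Idempotent at the same p.
    """
    if not 0.0 < p <= 1.0:
        raise ConfigurationError("p must lie in (0, 1]")
    total = g.n_nodes * (g.n_nodes - 1) / 2
    # epsilon guards float artefacts (0.2 * 15 = 3.0000000000000004)
    keep = max(1, min(int(np.ceil(p * total - 1e-9)), g.n_edges))
    order = _edge_sort_key(g)[:keep]
    order = np.sort(order)  # preserve canonical pair order in storage
    return replace(
        g,
        edge_index=g.edge_index[order],
        edge_weight=g.edge_weight[order],
        node_values=g.node_values.copy(),
        node_features=g.node_features.copy(),
        nodes=list(g.nodes),
    )


def _connected_at(g: PatientGraph, threshold: float) -> bool:
    mask = g.edge_weight >= threshold
    parent = np.arange(g.n_nodes)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for u, v in g.edge_index[mask]:
        ru, rv = find(int(u)), find(int(v))
        if ru != rv:
            parent[ru] = rv
    roots = {find(int(k)) for k in range(g.n_nodes)}
    return len(roots) == 1


def sparsify_min_connected(g: PatientGraph) -> PatientGraph:
    """Sparsest connected subgraph via binary search on the weight threshold.

    Finds the largest threshold t* (over the observed edge-weight values)
    such that keeping edges with w >= t* leaves the graph connected, then
    returns that subgraph.  Any strictly higher threshold disconnects it.
    Equivalent to keeping every edge at least as heavy as the bottleneck of
    a maximum spanning tree (used as an independent oracle in tests).
    """
    if not _connected_at(g, -np.inf):
        raise StructuralError("input graph is disconnected")
    levels = np.unique(g.edge_weight)
    lo, hi = 0, len(levels) - 1
    # invariant: levels[lo] keeps the graph connected
    if not _connected_at(g, levels[lo]):
        raise StructuralError("graph disconnected at the minimum weight level")
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if _connected_at(g, levels[mid]):
            lo = mid
        else:
            hi = mid - 1
    t_star = levels[lo]
    mask = g.edge_weight >= t_star
    return replace(
        g,
        edge_index=g.edge_index[mask],
        edge_weight=g.edge_weight[mask],
        node_values=g.node_values.copy(),
        node_features=g.node_features.copy(),
        nodes=list(g.nodes),
    )


def apply_sparsifier(g: PatientGraph, config: SparsifierConfig) -> PatientGraph:
    config.validate()
    if config.mode == "none":
        return g
    if config.mode == "top_p":
        return sparsify_top_p(g, config.p)
    return sparsify_min_connected(g)


def attach_node_topology(g: PatientGraph, edge_length: str = "hop") -> PatientGraph:
    """Attach the 5-vector (value, degree, strength, closeness, betweenness).

    Degree centrality is normalised by (N-1); strength is the sum of
    incident edge weights; closeness and betweenness are computed on the
    sparsified topology.  By default path lengths are unweighted hop counts
    (``edge_length='hop'``); ``'inv_weight'`` uses 1/w edge lengths instead.
    Disconnected graphs use the Wasserman–Faust reachable-set closeness
    convention, and betweenness is normalised by (N-1)(N-2)/2 over the full
    node set.
    """
    if edge_length not in ("hop", "inv_weight"):
        raise ConfigurationError(f"unknown edge_length {edge_length!r}")
    n = g.n_nodes
    nxg = nx.Graph()
    nxg.add_nodes_from(range(n))
    for (u, v), w in zip(g.edge_index, g.edge_weight):
        nxg.add_edge(int(u), int(v), weight=float(w), length=1.0 / max(w, 1e-12))
    dist_attr = None if edge_length == "hop" else "length"
    degree = np.array([nxg.degree(k) for k in range(n)], dtype=float)
    degree_c = degree / (n - 1) if n > 1 else np.zeros(n)
    strength = np.zeros(n)
    np.add.at(strength, g.edge_index[:, 0], g.edge_weight)
    np.add.at(strength, g.edge_index[:, 1], g.edge_weight)
    closeness = nx.closeness_centrality(nxg, distance=dist_attr, wf_improved=True)
    betweenness = nx.betweenness_centrality(nxg, normalized=True, weight=dist_attr)
    feats = np.column_stack(
        [
            g.node_values,
            degree_c,
            strength,
            np.array([closeness[k] for k in range(n)]),
            np.array([betweenness[k] for k in range(n)]),
        ]
    )
    return replace(g, node_features=feats)


def build_fold_graphs(
    train: FeatureTable,
    test: FeatureTable,
    n_selected: int,
    sparsifier: SparsifierConfig,
    use_topology: bool = True,
    seed: int = 0,
    edge_length: str = "hop",
    selected: Sequence[str] | None = None,
) -> tuple[list[PatientGraph], list[PatientGraph], dict]:
    """Fold orchestration: standardize, select, fit bank, build, sparsify.

    Selection, standardization and all pairwise models are derived from the
    training table only; test-fold construction reads test feature values
    but never test labels.  Returns (train graphs, test graphs, info) where
    info records the selected features and standardization parameters.
    """
    all_rows = np.arange(train.n_patients)
    params = zscore_fit(train, all_rows)
    train_std = zscore_apply(train, params)
    test_std = zscore_apply(test, params)
    if selected is None:
        ranking = mi_rank(train_std, all_rows, seed=seed)
        selected = select_top_n(ranking, n_selected)
    else:
        ranking = None
        selected = list(selected)
    bank = fit_pairwise_bank(train_std.subset_columns(selected), selected)
    train_graphs = build_patient_graphs(bank, train_std, attach_labels=True)
    test_graphs = build_patient_graphs(bank, test_std, attach_labels=False)

    def _finish(graph: PatientGraph) -> PatientGraph:
        out = apply_sparsifier(graph, sparsifier)
        if use_topology:
            out = attach_node_topology(out, edge_length=edge_length)
        return out

    info = {
        "selected": list(selected),
        "ranking": ranking,
        "standardization": params,
        "bank": bank,
    }
    return [_finish(g) for g in train_graphs], [_finish(g) for g in test_graphs], info
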