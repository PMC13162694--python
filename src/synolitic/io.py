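"""File I/O: feature tables (CSV), manifests (JSON), graphs (GraphML / CSV)."""

from __future__ import annotations

import json
import pathlib

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import FeatureTable
from .errors import StructuralError
from .graphs import NODE_FEATURE_NAMES, PatientGraph

__all__ = [
    "load_feature_table",
    "save_feature_table",
    "save_manifest",
    "export_patient_graph",
]


def load_feature_table(path) -> FeatureTable:
    """Read and validate a feature-table CSV.

    Requires a header with ``patient_id``, ``label`` (0/1) and at least two
    numeric feature columns; problems are reported with the offending row
    or column named.
    """
    path = pathlib.Path(path)
    try:
        df = pd.read_csv(path, dtype={"patient_id": str})
    except pd.errors.EmptyDataError:
        raise StructuralError(f"empty file: {path}") from None
    for required in ("patient_id", "label"):
        if required not in df.columns:
            raise StructuralError(f"missing required column {required!r}")
    feature_cols = [c for c in df.columns if c not in ("patient_id", "label")]
    if len(feature_cols) < 2:
        raise StructuralError("need at least 2 feature columns")
    dup = df["patient_id"][df["patient_id"].duplicated()]
    if len(dup):
        raise StructuralError(f"duplicated patient_id: {dup.iloc[0]!r}")
    if not df["label"].isin((0, 1)).all():
        bad = df.loc[~df["label"].isin((0, 1))].index[0]
        raise StructuralError(f"label must be 0/1 (row {bad})")
    values = np.empty((len(df), len(feature_cols)))
    for j, col in enumerate(feature_cols):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.index[numeric.isna()]
        if len(bad):
            raise StructuralError(
                f"non-numeric or missing value in column {col!r}, row {bad[0]}"
            )
        values[:, j] = numeric.to_numpy()
    table = FeatureTable(
        patient_ids=df["patient_id"].tolist(),
        feature_names=feature_cols,
        values=values,
        labels=df["label"].to_numpy(dtype=int),
        provenance=f"loaded from {path}",
    )
    table.validate()
    return table


def save_feature_table(table: FeatureTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def save_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)


def export_patient_graph(g: PatientGraph, out_dir) -> None:
    """Write GraphML, a ``u,v,w`` edge list and a node-attribute table."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nxg = g.to_networkx()
    nx.write_graphml(nxg, out / f"{g.patient_id}.graphml")
    edges = pd.DataFrame(
        {
            "u": [g.nodes[u] for u, _ in g.edge_index],
            "v": [g.nodes[v] for _, v in g.edge_index],
            "w": g.edge_weight,
        }
    )
    edges.to_csv(out / f"{g.patient_id}_edges.csv", index=False)
    cols = (
        NODE_FEATURE_NAMES
        if g.node_features.shape[1] == len(NODE_FEATURE_NAMES)
        else ("value",)
    )
    nodes = pd.DataFrame(g.node_features, columns=list(cols))
    nodes.insert(0, "feature", g.nodes)
    nodes.to_csv(out / f"{g.patient_id}_nodes.csv", index=False)
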