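import numpy as np
import pytest

from synolitic.cohort import SyntheticSpec, generate_cohort
from synolitic.graphs import PatientGraph


@pytest.fixture
def small_cohort():
    """120 patients, 12 features, two marginal signals."""
    spec = SyntheticSpec(
        n_patients=120,
        prevalence=0.25,
        n_features=12,
        block_structure=((4, 0.6),),
        marginal_effects=((4, 1.2), (5, 0.8)),
        seed=42,
    )
    table, manifest = generate_cohort(spec)
    return table, manifest, spec


@pytest.fixture
def noise_cohort():
    """Pure-noise cohort: no planted signal of any kind."""
    spec = SyntheticSpec(
        n_patients=100,
        prevalence=0.3,
        n_features=8,
        block_structure=(),
        seed=7,
    )
    table, _ = generate_cohort(spec)
    return table


def random_patient_graph(rng: np.random.Generator, n_nodes: int,
                         edge_prob: float = 0.6) -> PatientGraph:
    """A random weighted graph for oracle comparisons."""
    edges = [
        (i, j)
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < edge_prob
    ]
    if not edges:
        edges = [(0, 1)]
    edge_index = np.array(edges, dtype=int)
    weights = rng.uniform(0.05, 1.0, len(edges))
    values = rng.standard_normal(n_nodes)
    return PatientGraph(
        patient_id="toy",
        nodes=[f"f{k:02d}" for k in range(n_nodes)],
        node_values=values,
        edge_index=edge_index,
        edge_weight=weights,
        node_features=values.reshape(-1, 1),
    )

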