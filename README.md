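# synolitic

Per-patient feature graphs from pairwise-classifier confidences, with
graph-neural-network classification and conventional-ML benchmarking under
a leakage-safe cross-validation protocol.

## The problem

Radiomics studies of cancer progression — for example, predicting which
active-surveillance prostate cancer patients will progress from a baseline
MRI — produce tabular data: a few hundred patients, ~75 continuous
features (texture/intensity/shape statistics plus clinical variables such
as PSA density), and an imbalanced binary outcome.  Conventional models
treat the features as independent columns.  The *synolitic* approach asks
whether the **relationships between feature pairs** carry additional
signal: each patient becomes a weighted graph whose nodes are features and
whose edges encode how confidently a classifier trained on that feature
pair separates the outcome classes *at this patient's values*:

    w_ij = 2 · |P(y = 1 | f_i, f_j) − 0.5| ∈ [0, 1]

with one two-feature logistic model per pair, fit inside the current
training fold.  The graphs are sparsified (top-p by confidence, or the
sparsest connected threshold), annotated with topological node features
(value, degree, strength, closeness, betweenness), and classified
end-to-end with a GCN or GATv2 — or summarised into fixed graph statistics
for conventional classifiers ("simplified" variant).  Everything is
evaluated under 5-fold stratified CV in which no fitting step ever touches
a test-fold row.

Because cohorts of this kind are typically not deposited, the package
ships a first-class synthetic cohort generator with controllable marginal
effects, pure pairwise-interaction effects (sign-product construction),
correlated feature blocks, class imbalance, and perturbed replicate tables
for ICC-based robustness filtering.  See `docs/methods.md` for the full
model description and design choices.

## Worked example

A cohort in which the outcome is carried almost entirely by pairwise
feature coupling (sign products of planted feature pairs), with every
single feature near-uninformative on its own (univariate AUC ≈ 0.5):

```python
import dataclasses
from synolitic import (SyntheticSpec, generate_cohort, ExperimentConfig,
                       SparsifierConfig, GNNConfig, run_cv_experiment)

spec = SyntheticSpec(                    # 343 patients, 21.3% positives
    n_features=20, block_structure=(),
    interaction_effects=tuple((2 * k, 2 * k + 1, 1.0) for k in range(10)),
    marginal_effects=tuple((i, 0.12) for i in range(0, 20, 2)),
    interaction_magnitude_ratio=1.3,
    seed=1,
)
table, truth = generate_cohort(spec)

config = ExperimentConfig(
    arm="gatv2", n_selected=20,
    sparsifier=SparsifierConfig("top_p", 0.8), node_topology=True,
    gnn=GNNConfig(architecture="gatv2", hidden_dim=32, max_epochs=12,
                  inner_val_fraction=0.0, learning_rate=3e-3, dropout=0.1),
    seed=1,
)
result = run_cv_experiment(table, config)
print(result.experiment_id, result.aggregate())

lr = run_cv_experiment(table, dataclasses.replace(config, arm="lr"))
print(lr.experiment_id, lr.aggregate())
```

prints:

```
gatv2|top_p(0.8)|5dim|n20 {'auc_mean': 0.9080, 'auc_sd': 0.0583,
'f1_mean': 0.6771, 'f1_sd': 0.0750, 'accuracy_mean': 0.8455,
'accuracy_sd': 0.0419}
lr {'auc_mean': 0.5495, 'auc_sd': 0.0979, 'f1_mean': 0.3161,
'f1_sd': 0.0814, 'accuracy_mean': 0.5569, 'accuracy_sd': 0.0699}
```

(digits shown to 4 places): the graph-attention arm cross-validates at
ROC-AUC 0.91 ± 0.06 while logistic regression on the same raw features —
same folds, so the comparison is paired — sits at 0.55 ± 0.10.  The
pairwise structure, invisible to any model that treats features as
independent columns, is exactly what the per-patient graphs expose.  On
cohorts whose signal is mostly *marginal* the ordering reverses
(conventional models lead; see the acceptance output below) — the graph
pipeline is a tool for relational signal, not a universal upgrade.

## Command line

```bash
synolitic simulate --config cohort.yaml --out data/ --seed 1
synolitic graphs --table data/cohort.csv --n-features 30 --sparsify top_p --p 0.8 --out graphs/
synolitic baselines --table data/cohort.csv --models gb,rf,svm,lr --out runs/conv
synolitic train --table data/cohort.csv --arch gatv2 --trials 8 --out runs/gatv2
synolitic simplified-sgnn --table data/cohort.csv --model gb --out runs/sgnn_gb
synolitic evaluate --config grid.yaml --table data/cohort.csv --out runs/grid
synolitic report --in runs/grid
```

Graphs export as GraphML plus `u,v,w` edge-list and node-attribute CSVs;
results as per-fold and aggregate CSVs with a ranked bar chart.

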