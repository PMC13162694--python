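# Methods

## The model

The pipeline targets a common situation in clinical radiomics: a few
hundred patients, a binary outcome with minority prevalence around 20%,
and a tabular pool of ~75 continuous features (texture, intensity and
shape statistics from two MRI contrasts plus a handful of clinical
variables) whose individual discriminative power is modest.  The working
hypothesis is that *relationships between feature pairs* carry information
beyond the features' raw values.

Each patient is represented as a **synolitic graph**:

1. **Selection.** Within a training fold, features are ranked by mutual
   information with the outcome (k-nearest-neighbour estimator, k = 3,
   seeded) and the top N are kept (N ∈ {20, 30, 40}).
2. **Pairwise model bank.** For every unordered pair of selected features,
   a two-feature logistic regression (L-BFGS, ≤ 1000 iterations, L2 with
   C = 1.0, no class weighting) is fit on the standardized training fold —
   N(N−1)/2 models in total.
3. **Edge weights.** For a given patient with standardized values
   (f_i, f_j), the edge between nodes i and j carries

       w_ij = 2 · |P(y = 1 | f_i, f_j) − 0.5| ∈ [0, 1],

   the confidence of the pair's classifier at this patient's values.
   The direction of the vote is deliberately discarded.
4. **Sparsification.** Three strategies: none (complete graph); *top-p*
   (keep the ⌈p · N(N−1)/2⌉ highest-confidence edges, p ∈ {0.2, 0.8},
   ties broken lexicographically by endpoint names); *minimum connected*
   (binary search for the largest weight threshold that keeps the graph
   connected — equivalently, the bottleneck weight of a maximum spanning
   tree, which the test suite uses as an independent oracle).
5. **Node features.** Either the standardized value alone (1-dim) or a
   5-vector: value, degree centrality (normalised by N−1), weighted
   strength, closeness, and betweenness centrality.
6. **Classification.** Graph-level binary classification by a 3-layer GCN
   or GATv2, or — in the "simplified" variant — fixed graph summary
   statistics fed to gradient boosting / random forest.

Everything upstream of test-fold scoring (standardization, MI ranking,
pairwise models, hyperparameter tuning, classifier training) is fit
strictly inside the training fold of a 5-fold stratified CV; test-fold
labels are never read during graph construction, and every fitting routine
reports the rows it consumed to a leakage instrumentation layer that the
tests interrogate.

## Network architectures

Both architectures are implemented on a small vectorized reverse-mode
autodiff engine written for this package (`synolitic.nn.autograd`,
float32 by default, gradient-checked against finite differences in
float64).  Patient graphs have ≤ 40 nodes, so CPU numpy is entirely
adequate; message passing uses precomputed sparse selection matrices
rather than scatter loops.

Shared skeleton: 3 message-passing layers, an edge-encoder MLP
(1 → 16 → out) per layer, batch normalisation, ReLU, dropout, and a
residual connection per layer; readout concatenates graph-wide mean and
max pooling; a two-layer head produces 2 logits.

* **GCN variant**: the edge encoder maps w to a positive scalar via
  softplus; aggregation is the coefficient-weighted neighbour sum plus a
  unit self-term, normalised by the total coefficient mass.
* **GATv2 variant**: dynamic attention with 4 heads.  Per edge,
  e = LeakyReLU(W_src h_i + W_dst h_j + E(w)); scores are per-head inner
  products, softmax-normalised over each node's in-edges.  Heads are
  concatenated in layers 1–2 and averaged in layer 3.  All heads are
  evaluated in one fused pass (block-diagonal attention matrix).

Training: Adam; class-weighted cross-entropy with the "balanced"
convention w_c = n/(2 n_c); optional early stopping on a stratified
inner-validation ROC-AUC with configurable patience.  Defaults
(max_epochs 200, patience 20, batch 32, inner validation fraction 0.2)
are training-protocol choices, all configurable; the desk-scale
experiments in the test-suite and acceptance script use reduced epochs
(documented below).

Hyperparameter search runs strictly inside each CV training fold as a
seeded random search over hidden ∈ {32, 64, 128}, dropout ∈ [0, 0.5],
log-uniform learning rate ∈ [1e-4, 1e-2], 8 trials by default, maximising
inner-validation ROC-AUC, followed by a refit on the full training fold.

## Synthetic cohorts

Real cohorts of this kind are rarely shareable, so the generator is a
first-class module.  It emulates:

* exact class counts — positives = round(prevalence · n), assigned by
  permutation (default n = 343, prevalence 0.213 → 73 positives);
* correlated feature blocks (equicorrelated Gaussians via a shared
  factor), mimicking the redundancy of texture-feature families; the
  default layout covers 56 of 75 features in six blocks (ρ 0.3–0.7);
* marginal effects — a standardized between-class mean shift d, giving a
  population univariate ROC-AUC of Φ(d/√2);
* pairwise interaction effects — a pair whose *sign product* equals the
  class sign with probability (1+s)/2, while each member stays marginally
  symmetric about zero (the canonical jointly-informative,
  marginally-silent construction); a linear model on the pair sees
  nothing, a model with a product term recovers AUC = (1+s)/2.  An
  optional magnitude ratio puts positive-class members on a modestly
  larger magnitude scale (the negative-class scale is solved so the
  mixture variance stays 1); each member's distribution remains symmetric,
  so its univariate rank AUC stays exactly at chance and linear models
  remain blind, while pairwise and graph-structural signal strengthens;
* perturbed replicate tables (additive Gaussian measurement noise) for
  ICC-based robustness filtering, emulating segmentation-perturbation
  re-measurements; the image-level perturbation itself is out of scope.

One global seed fans out to named substreams (labels, features,
interactions, replicates), so e.g. requesting replicates never changes
the cohort draw.  Feature names follow a radiomics-like scheme
(`t2w_glcm_f01`, …, `clin_psad`) so modality-aware reporting is testable.

What the generator does **not** model: real radiomic marginal
distributions (heavy tails, boundedness), scanner effects, non-Gaussian
dependence, censoring. Passing tests on these cohorts therefore
demonstrate correctness and calibration of the machinery, not clinical
performance.

## Preprocessing conventions

* **ICC filter**: two-way, absolute-agreement, single-measurement
  variance-components ICC (ICC(2,1)-style; cross-checked against
  `pingouin` ICC(A,1) in tests).  Strictly greater than the cutoff (0.8)
  is retained; replicate order is immaterial.
* **Standardization**: per-feature z-score with sample SD (ddof = 1),
  fit on training rows only; constant training columns raise an error
  naming the feature.  Clinical and radiomic columns are standardized
  uniformly.
* **MI ranking**: kNN estimator (k = 3), seeded; ties broken
  lexicographically by feature name.

## Numerical and design choices

* Top-p ranks edges by w itself (w is strictly monotone in the
  classifier's confidence |P − 0.5|, so the ranking is unambiguous); the
  edge budget is a fraction of the complete-graph edge count, which makes
  the operation idempotent, and an epsilon guards binary-float artefacts
  in the ceiling (0.2 · 15 must keep 3 edges, not 4).
* Path-based centralities use unweighted hop distances on the sparsified
  topology by default; a weight-to-length mapping (1/w) is available via
  `edge_length="inv_weight"` but any such mapping is arbitrary, so hop
  distance is the documented default.  Centralities are computed *after*
  sparsification — they describe the graph the classifier sees.
* Disconnected graphs: Wasserman–Faust reachable-set closeness;
  betweenness normalised by (N−1)(N−2)/2 over the full node set.
* Minimum-connected sparsification is implemented as the stated binary
  search over the sorted unique weight levels; the bottleneck-MST identity
  is used only as a test oracle.
* SVM probabilities come from a monotone (Platt) calibration of the
  decision margin fit on the training fold; ROC-AUC is invariant to any
  strictly monotone mapping, F1/accuracy gain a usable 0.5 threshold.
* F1 and accuracy threshold the positive-class probability at 0.5 (no
  threshold is canonical for this protocol; documented, configurable).
* Mann–Whitney U: exact null distribution for small tie-free groups
  (both ≤ 20), otherwise normal approximation with tie/continuity
  correction.
* Fold SD uses ddof = 1 across the 5 fold values.  No confidence
  intervals are reported: with 4 degrees of freedom, t-based intervals
  are too wide to be informative; fold-to-fold SD is the honest summary.
* Folds are shared across arms for a given experiment seed, so arm
  comparisons are paired.
* The graph-summary vector for the simplified pipeline is frozen as
  schema v1 (23 dimensions): mean/SD/max of the four node centralities,
  four global properties (edge count, density, component count, largest
  component), and seven edge-weight statistics (mean, SD, min, max,
  quartiles).

## Desk-scale experiment sizes

The heavy end-to-end checks run at deliberately chosen reduced sizes, as
this package's own protocol:

* **Null calibration**: 10 pure-noise cohorts (n = 343, 75 features,
  21.3% prevalence), all eight arms, N = 20 selection with
  minimum-connected sparsification and 3-epoch network training — a null
  stays a null regardless of training length, so short schedules are
  sufficient and keep the suite fast.
* **Interaction recovery**: cohorts of 20 features carrying ten planted
  sign-product pairs (deterministic within-pair coupling, positive-class
  magnitude ratio 1.3) and a weak marginal nudge (d = 0.12, univariate
  AUC ≈ 0.53) on one member of each pair — enough to give the pairwise
  edge weights (and hence the topological node features) real signal
  without lifting any single feature out of the near-uninformative band.
  The network arm uses a fixed mid-range configuration (GATv2, hidden 32,
  dropout 0.1, lr 3e-3, 12 epochs) rather than the full 8-trial search.
  A caveat this experiment family exposes: the topological node features
  are deterministic functions of edge weights the network already
  receives, so in synthetic cohorts they add representation, not
  information — the measured 5-dim-vs-1-dim difference is small and
  seed-sensitive, unlike the marginal-rich real-data regime.  With
  every feature a pair member, the label is recoverable from an
  *edge-symmetric* statistic (the sum of per-edge sign products), which
  the attention architecture can represent without having to identify
  individual nodes; this matters because message passing plus pooling is
  permutation-invariant, so a label carried by a handful of anonymous
  node pairs among many is provably invisible to it when nodes are
  statistically indistinguishable.  A 20-feature pool (all selected at
  N = 20) keeps the selection stage from randomly discarding marginally
  silent pair members.  The network arm uses a fixed mid-range
  configuration (GATv2, hidden 64, dropout 0.1, lr 3e-3, 24 epochs,
  no inner split) rather than the full 8-trial search.
* **Acceptance script**: one reference cohort per seed with mixed
  marginal + interaction signal (strongest marginal on the PSA-density
  analogue), seven arms under shared 5-fold CV, N = 20, 20-epoch network
  training.

## Known limitations

* The Gaussian-block cohort model is a stand-in; no claim is made that it
  reproduces real radiomic feature distributions.
* The network arms are deterministic given a seed on a fixed platform;
  across BLAS builds, float32 accumulation order may differ in the last
  ulps.
* Batch normalisation uses running statistics at evaluation; very small
  training batches (< 16) are not recommended.
* The pairwise edge machinery is linear per pair by construction
  (faithful to the method); purely epistatic pair signals therefore enter
  the graphs only through node values, not edge weights.
* No formal statistical comparison between arms is performed, and no
  calibration/decision-curve analysis is included.
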