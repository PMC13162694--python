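"""Training, prediction and hyperparameter search for the graph classifiers.

Training uses Adam on class-weighted cross-entropy (weights n/(2*n_c),
the "balanced" convention) with early stopping on inner-validation ROC-AUC.
Everything is driven by named substreams of one seed, so a fixed seed gives
an identical loss trace across runs.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from sklearn.model_selection import train_test_split

from .._rng import subseed, substream
from ..errors import ConfigurationError
from ..graphs import PatientGraph
from ..instrument import record_fit_rows
from ..metrics import roc_auc
from . import autograd as ag
from .config import DROPOUT_RANGE, HIDDEN_CHOICES, LR_RANGE, GNNConfig, SearchBudget
from .layers import Adam
from .models import GNNModel, build_model, collate

__all__ = ["train", "tune", "predict_proba", "class_weights", "sample_config"]


def class_weights(labels: np.ndarray) -> np.ndarray:
    """Inverse-frequency weights w_c = n / (2 * n_c)."""
    y = np.asarray(labels, dtype=int)
    n = len(y)
    counts = np.bincount(y, minlength=2)
    if counts.min() == 0:
        raise ConfigurationError("both classes required for class weighting")
    return n / (2.0 * counts)


def predict_proba(model: GNNModel, graphs: list[PatientGraph],
                  batch_size: int = 256) -> np.ndarray:
    """Positive-class probabilities; batch-size independent in eval mode."""
    out = []
    with ag.no_grad():
        for lo in range(0, len(graphs), batch_size):
            batch = collate(graphs[lo : lo + batch_size])
            logits = model.forward(batch, training=False)
            out.append(ag.softmax_rows(logits.data)[:, 1])
    return np.concatenate(out).astype(np.float64)


def train(
    model: GNNModel,
    graphs: list[PatientGraph],
    labels: np.ndarray | None = None,
    config: GNNConfig | None = None,
) -> tuple[GNNModel, list[dict]]:
    """Fit the model; returns (model, per-epoch history).

    If ``config.inner_val_fraction`` > 0, a stratified validation split is
    carved out of the given graphs for early stopping on ROC-AUC with the
    configured patience; the best-validation parameters are restored at the
    end.
    """
    config = config or model.config
    if labels is None:
        labels = np.array([g.label for g in graphs], dtype=int)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ConfigurationError("training requires both classes")
    record_fit_rows("gnn_train", (g.patient_id for g in graphs))
    model.set_input_stats(graphs)

    idx = np.arange(len(graphs))
    if config.inner_val_fraction > 0:
        tr_idx, val_idx = train_test_split(
            idx,
            test_size=config.inner_val_fraction,
            stratify=labels,
            random_state=subseed(config.seed, "early_stop_split"),
        )
    else:
        tr_idx, val_idx = idx, np.empty(0, dtype=int)

    tr_graphs = [graphs[i] for i in tr_idx]
    tr_labels = labels[tr_idx]
    val_graphs = [graphs[i] for i in val_idx]
    val_labels = labels[val_idx]
    weights = class_weights(tr_labels) if config.class_weighting else np.ones(2)

    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    shuffle_rng = substream(config.seed, "shuffle")
    dropout_rng = substream(config.seed, "dropout")

    history: list[dict] = []
    best_auc, best_state, since_best = -np.inf, None, 0
    for epoch in range(config.max_epochs):
        order = shuffle_rng.permutation(len(tr_graphs))
        losses = []
        for lo in range(0, len(order), config.batch_size):
            sel = order[lo : lo + config.batch_size]
            batch = collate([tr_graphs[i] for i in sel])
            logits = model.forward(batch, training=True, rng=dropout_rng)
            loss = ag.softmax_cross_entropy(logits, tr_labels[sel], weights)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
        row = {"epoch": epoch, "loss": float(np.mean(losses))}
        if len(val_graphs) and len(np.unique(val_labels)) == 2:
            val_auc = roc_auc(predict_proba(model, val_graphs), val_labels)
            row["val_auc"] = val_auc
            if val_auc > best_auc + 1e-9:
                best_auc, best_state, since_best = val_auc, model.state(), 0
            else:
                since_best += 1
                if since_best >= config.patience:
                    history.append(row)
                    break
        history.append(row)
    if best_state is not None:
        model.load_state(best_state)
    return model, history


def sample_config(base: GNNConfig, rng: np.random.Generator) -> GNNConfig:
    """Draw one configuration from the search space."""
    return replace(
        base,
        hidden_dim=int(rng.choice(HIDDEN_CHOICES)),
        dropout=float(rng.uniform(*DROPOUT_RANGE)),
        learning_rate=float(np.exp(rng.uniform(np.log(LR_RANGE[0]),
                                               np.log(LR_RANGE[1])))),
    )


def tune(
    graphs: list[PatientGraph],
    labels: np.ndarray,
    base_config: GNNConfig,
    budget: SearchBudget,
    node_dim: int,
) -> tuple[GNNConfig, GNNModel, list[dict]]:
    """Seeded random search over the stated space, inside a training fold.

    Each trial trains with the candidate configuration and is scored by its
    best inner-validation ROC-AUC; the argmax configuration (ties: first
    sampled) is refit on the full training fold and returned.
    """
    budget.validate()
    labels = np.asarray(labels, dtype=int)
    if budget.n_trials == 1:
        # degenerate budget: the base configuration is the single trial
        model = build_model(base_config, node_dim)
        _, history = train(model, graphs, labels, base_config)
        score = max((h.get("val_auc", -np.inf) for h in history),
                    default=-np.inf)
        return base_config, model, [{"trial": 0, "val_auc": score}]
    rng = substream(budget.sampler_seed, "sampler")
    trials: list[dict] = []
    best_cfg, best_score = None, -np.inf
    for t in range(budget.n_trials):
        cfg = sample_config(base_config, rng)
        cfg.validate(strict_space=True)
        model = build_model(cfg, node_dim)
        _, history = train(model, graphs, labels, cfg)
        score = max((h.get("val_auc", -np.inf) for h in history), default=-np.inf)
        trials.append(
            {
                "trial": t,
                "hidden_dim": cfg.hidden_dim,
                "dropout": cfg.dropout,
                "learning_rate": cfg.learning_rate,
                "val_auc": score,
            }
        )
        if score > best_score:
            best_score, best_cfg = score, cfg
    final = build_model(best_cfg, node_dim)
    train(final, graphs, labels, best_cfg)
    return best_cfg, final, trials
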