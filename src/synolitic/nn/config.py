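"""Configuration for the graph classifiers and their hyperparameter search."""

from __future__ import annotations

from dataclasses import dataclass, replace

from ..errors import ConfigurationError

HIDDEN_CHOICES = (32, 64, 128)
DROPOUT_RANGE = (0.0, 0.5)
LR_RANGE = (1e-4, 1e-2)


@dataclass(frozen=True)
class GNNConfig:
    """One graph-classifier configuration.

    The search space is hidden_dim in {32, 64, 128}, dropout in [0, 0.5],
    learning rate in [1e-4, 1e-2]; 3 message-passing layers throughout.
    Epochs/patience/batch size are training-protocol choices, not searched.
    """

    architecture: str = "gatv2"  # {"gcn", "gatv2"}
    hidden_dim: int = 64
    dropout: float = 0.2
    learning_rate: float = 1e-3
    n_layers: int = 3
    heads: int = 4
    max_epochs: int = 200
    patience: int = 20
    batch_size: int = 32
    inner_val_fraction: float = 0.2
    class_weighting: bool = True
    seed: int = 0

    def validate(self, strict_space: bool = False) -> None:
        if self.architecture not in ("gcn", "gatv2"):
            raise ConfigurationError(f"unknown architecture {self.architecture!r}")
        if strict_space:
            if self.hidden_dim not in HIDDEN_CHOICES:
                raise ConfigurationError(f"hidden_dim must be one of {HIDDEN_CHOICES}")
            if not DROPOUT_RANGE[0] <= self.dropout <= DROPOUT_RANGE[1]:
                raise ConfigurationError("dropout outside the search range")
            if not LR_RANGE[0] <= self.learning_rate <= LR_RANGE[1]:
                raise ConfigurationError("learning_rate outside the search range")
        if self.n_layers < 1 or self.max_epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("n_layers, max_epochs, batch_size must be >= 1")
        if not 0.0 <= self.inner_val_fraction < 1.0:
            raise ConfigurationError("inner_val_fraction must lie in [0, 1)")

    def with_seed(self, seed: int) -> "GNNConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class SearchBudget:
    """Random-search budget for inner-fold hyperparameter tuning."""

    n_trials: int = 8
    sampler_seed: int = 0

    def validate(self) -> None:
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
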