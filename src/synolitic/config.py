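"""Experiment configuration: one arm of the benchmark grid.

The full grid is 2 architectures x 3 sparsifiers x 2 node-feature settings
for the graph networks, plus 4 conventional baselines and the simplified
graph-summary variants — all expressible through this one dataclass (and
through YAML for the command line).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields

import yaml

from .errors import ConfigurationError
from .graphs import SparsifierConfig
from .nn.config import GNNConfig, SearchBudget

__all__ = ["ExperimentConfig", "load_experiment_config"]

VALID_ARMS = ("gcn", "gatv2", "gb", "rf", "svm", "lr", "sgnn_gb", "sgnn_rf")
N_SELECTED_CHOICES = (20, 30, 40)


@dataclass(frozen=True)
class ExperimentConfig:
    arm: str = "gatv2"
    n_selected: int = 30
    sparsifier: SparsifierConfig = field(default_factory=SparsifierConfig)
    node_topology: bool = True
    gnn: GNNConfig = field(default_factory=GNNConfig)
    search: SearchBudget | None = None
    k_folds: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.arm not in VALID_ARMS:
            raise ConfigurationError(f"unknown arm {self.arm!r}")
        self.sparsifier.validate()
        if self.arm in ("gcn", "gatv2"):
            if self.gnn.architecture != self.arm:
                raise ConfigurationError(
                    f"arm {self.arm!r} requires gnn.architecture {self.arm!r}"
                )
            self.gnn.validate()
            if self.search is not None:
                self.search.validate()
        elif self.search is not None:
            raise ConfigurationError("search budget only applies to GNN arms")
        if self.k_folds < 2:
            raise ConfigurationError("k_folds must be >= 2")

    def experiment_id(self) -> str:
        if self.arm in ("gcn", "gatv2"):
            nf = "5dim" if self.node_topology else "1dim"
            return f"{self.arm}|{self.sparsifier.tag()}|{nf}|n{self.n_selected}"
        if self.arm in ("sgnn_gb", "sgnn_rf"):
            return f"{self.arm}|{self.sparsifier.tag()}|n{self.n_selected}"
        return self.arm

    def fingerprint(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_dict(self) -> dict:
        d: dict = {
            "arm": self.arm,
            "n_selected": self.n_selected,
            "sparsifier": {"mode": self.sparsifier.mode, "p": self.sparsifier.p},
            "node_topology": self.node_topology,
            "k_folds": self.k_folds,
            "seed": self.seed,
        }
        if self.arm in ("gcn", "gatv2"):
            d["gnn"] = {
                f.name: getattr(self.gnn, f.name) for f in fields(self.gnn)
            }
            if self.search is not None:
                d["search"] = {
                    "n_trials": self.search.n_trials,
                    "sampler_seed": self.search.sampler_seed,
                }
        return d


def _build_config(raw: dict) -> ExperimentConfig:
    known = {
        "arm", "n_selected", "sparsifier", "node_topology", "gnn",
        "search", "k_folds", "seed",
    }
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict = {k: raw[k] for k in ("arm", "n_selected", "node_topology",
                                        "k_folds", "seed") if k in raw}
    if "sparsifier" in raw:
        sp = raw["sparsifier"]
        unknown_sp = set(sp) - {"mode", "p"}
        if unknown_sp:
            raise ConfigurationError(f"unknown sparsifier keys: {sorted(unknown_sp)}")
        kwargs["sparsifier"] = SparsifierConfig(**sp)
    if "gnn" in raw:
        valid = {f.name for f in fields(GNNConfig)}
        unknown_g = set(raw["gnn"]) - valid
        if unknown_g:
            raise ConfigurationError(f"unknown gnn keys: {sorted(unknown_g)}")
        kwargs["gnn"] = GNNConfig(**raw["gnn"])
    elif raw.get("arm") in ("gcn", "gatv2"):
        kwargs["gnn"] = GNNConfig(architecture=raw["arm"])
    if "search" in raw and raw["search"] is not None:
        unknown_s = set(raw["search"]) - {"n_trials", "sampler_seed"}
        if unknown_s:
            raise ConfigurationError(f"unknown search keys: {sorted(unknown_s)}")
        kwargs["search"] = SearchBudget(**raw["search"])
    elif raw.get("arm") in ("gcn", "gatv2"):
        # declared experiments must state their tuning budget explicitly
        # (use n_trials: 1 for a fixed configuration)
        raise ConfigurationError(
            f"arm {raw['arm']!r} requires a search budget (search.n_trials)"
        )
    config = ExperimentConfig(**kwargs)
    config.validate()
    return config


def load_experiment_config(path) -> list[ExperimentConfig]:
    """Load one or many experiment configs from a YAML file.

    The file is either a single mapping or ``{"experiments": [...]}``.
    Unknown keys are rejected with an error listing them.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raise ConfigurationError(f"empty config file: {path}")
    if isinstance(raw, dict) and "experiments" in raw:
        extra = set(raw) - {"experiments"}
        if extra:
            raise ConfigurationError(f"unknown top-level keys: {sorted(extra)}")
        return [_build_config(item) for item in raw["experiments"]]
    return [_build_config(raw)]
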