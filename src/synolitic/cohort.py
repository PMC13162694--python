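"""Synthetic patient cohorts with controllable signal structure.

The generator emulates the statistical shape of a radiomics feature table
from an active-surveillance cohort: a few hundred patients, ~75 continuous
features organised in correlated blocks (texture families from the same
image modality are highly redundant), a minority positive class
(progressors), and three kinds of planted signal:

* marginal effects — a standardized mean shift ``d`` between classes on a
  named feature;
* pairwise interaction effects — a feature pair whose *sign product* tracks
  the label while each member stays marginally (near-)uninformative, the
  canonical jointly-informative / marginally-silent construction;
* pure noise — everything else.

Replicate tables with additive measurement noise emulate perturbed
re-measurements for ICC-based robustness filtering.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .errors import ConfigurationError, StructuralError

__all__ = [
    "SyntheticSpec",
    "FeatureTable",
    "generate_cohort",
    "generate_perturbed_replicates",
    "default_feature_names",
]

#: Default correlated-block layout: six "texture family" blocks covering 56
#: of 75 features; the remaining 19 are independent.
DEFAULT_BLOCKS: tuple[tuple[int, float], ...] = (
    (10, 0.7),
    (10, 0.7),
    (10, 0.5),
    (10, 0.5),
    (8, 0.3),
    (8, 0.3),
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic cohort draw.

    Parameters mirror the cohort the pipeline targets: 343 patients at
    21.3% positive prevalence over a 75-feature pool.
    """

    n_patients: int = 343
    prevalence: float = 0.213
    n_features: int = 75
    block_structure: tuple[tuple[int, float], ...] = DEFAULT_BLOCKS
    marginal_effects: tuple[tuple[int, float], ...] = ()
    #: (feature_i, feature_j, strength in [0,1]); strength s means the pair's
    #: sign product equals the class sign with probability (1+s)/2.
    interaction_effects: tuple[tuple[int, int, float], ...] = ()
    #: magnitude scale of interaction members in the positive class; the
    #: negative-class scale is set so the mixture variance stays 1.  Each
    #: member's distribution remains symmetric about 0, so its univariate
    #: rank discrimination stays exactly at chance.
    interaction_magnitude_ratio: float = 1.0
    noise_sd: float = 1.0
    n_replicates: int = 0
    replicate_noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ConfigurationError("n_patients must be >= 2")
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigurationError("prevalence must lie in (0, 1)")
        if self.n_features < 1:
            raise ConfigurationError("n_features must be >= 1")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.replicate_noise_sd < 0:
            raise ConfigurationError("replicate_noise_sd must be non-negative")
        if self.n_replicates < 0:
            raise ConfigurationError("n_replicates must be >= 0")
        if sum(b for b, _ in self.block_structure) > self.n_features:
            raise ConfigurationError("block sizes exceed n_features")
        for b, rho in self.block_structure:
            if b < 1 or not 0.0 <= rho < 1.0:
                raise ConfigurationError(f"invalid block ({b}, {rho})")
        for idx, _d in self.marginal_effects:
            if not 0 <= idx < self.n_features:
                raise ConfigurationError(f"marginal effect index {idx} out of range")
        for i, j, s in self.interaction_effects:
            if i == j:
                raise ConfigurationError("interaction pair must use distinct features")
            if not (0 <= i < self.n_features and 0 <= j < self.n_features):
                raise ConfigurationError(f"interaction pair ({i}, {j}) out of range")
            if not 0.0 <= s <= 1.0:
                raise ConfigurationError("interaction strength must lie in [0, 1]")
        if self.interaction_magnitude_ratio <= 0:
            raise ConfigurationError("interaction_magnitude_ratio must be positive")
        if self.prevalence * self.interaction_magnitude_ratio**2 >= 1.0:
            raise ConfigurationError(
                "interaction_magnitude_ratio too large for this prevalence"
            )
        if self.n_positive < 1:
            raise ConfigurationError(
                "prevalence * n_patients rounds to fewer than one positive"
            )

    @property
    def n_positive(self) -> int:
        return int(round(self.prevalence * self.n_patients))


@dataclass
class FeatureTable:
    """Patients x features with binary labels — the pipeline's universal input."""

    patient_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    labels: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)

    def validate(self, require_both_classes: bool = False) -> None:
        n, p = self.values.shape
        if len(self.patient_ids) != n:
            raise StructuralError("patient_ids length does not match value rows")
        if len(self.feature_names) != p:
            raise StructuralError("feature_names length does not match value columns")
        if len(set(self.patient_ids)) != n:
            raise StructuralError("duplicate patient ids")
        if len(set(self.feature_names)) != p:
            raise StructuralError("duplicate feature names")
        if not np.all(np.isfinite(self.values)):
            raise StructuralError("values contain missing or non-finite entries")
        if not np.isin(self.labels, (0, 1)).all():
            raise StructuralError("labels must be 0/1")
        if require_both_classes and len(np.unique(self.labels)) < 2:
            raise StructuralError("labels must contain both classes")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_rows(self, rows: Sequence[int]) -> "FeatureTable":
        rows = np.asarray(rows, dtype=int)
        return FeatureTable(
            [self.patient_ids[i] for i in rows],
            list(self.feature_names),
            self.values[rows],
            self.labels[rows],
            self.provenance,
        )

    def subset_columns(self, names: Sequence[str]) -> "FeatureTable":
        index = {f: k for k, f in enumerate(self.feature_names)}
        missing = [f for f in names if f not in index]
        if missing:
            raise StructuralError(f"unknown features: {missing}")
        cols = [index[f] for f in names]
        return FeatureTable(
            list(self.patient_ids),
            list(names),
            self.values[:, cols],
            self.labels.copy(),
            self.provenance,
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            list(self.patient_ids),
            list(self.feature_names),
            self.values.copy(),
            self.labels.copy(),
            self.provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "patient_id", self.patient_ids)
        df.insert(1, "label", self.labels)
        return df


def default_feature_names(n_features: int) -> list[str]:
    """Radiomics-flavoured feature names.

    The last three columns take clinical names (gland volume, PSA, PSA
    density) when the pool is large enough to plausibly contain them.
    """
    families = [
        "t2w_firstorder",
        "t2w_glcm",
        "t2w_glrlm",
        "t2w_glszm",
        "adc_firstorder",
        "adc_glcm",
        "adc_gldm",
        "adc_shape",
    ]
    clinical = ["clin_volume", "clin_psa", "clin_psad"]
    n_radiomic = n_features - len(clinical) if n_features >= 10 else n_features
    names = [
        f"{families[k % len(families)]}_f{k:02d}" for k in range(n_radiomic)
    ]
    if n_radiomic < n_features:
        names.extend(clinical)
    return names


def _draw_labels(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    labels = np.zeros(spec.n_patients, dtype=np.int64)
    labels[: spec.n_positive] = 1
    rng.shuffle(labels)
    return labels


def _draw_base_features(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian features with equicorrelated blocks."""
    n, p = spec.n_patients, spec.n_features
    x = np.empty((n, p))
    col = 0
    for size, rho in spec.block_structure:
        shared = rng.standard_normal((n, 1))
        eps = rng.standard_normal((n, size))
        x[:, col : col + size] = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps
        col += size
    if col < p:
        x[:, col:] = rng.standard_normal((n, p - col))
    return x


def generate_cohort(spec: SyntheticSpec) -> tuple[FeatureTable, dict]:
    """Draw a labelled cohort; returns the table and a ground-truth manifest.

    Deterministic given ``spec.seed``.  The positive count is exact
    (``round(prevalence * n)``), assigned by permutation rather than
    Bernoulli draws so fold arithmetic is reproducible.  ``noise_sd`` scales
    every feature; effect sizes are standardized (in units of ``noise_sd``),
    so a marginal shift ``d`` yields a population univariate ROC-AUC of
    ``Phi(d / sqrt(2))``.
    """
    spec.validate()
    labels = _draw_labels(spec, substream(spec.seed, "labels"))
    x = _draw_base_features(spec, substream(spec.seed, "features"))

    for idx, d in spec.marginal_effects:
        x[:, idx] = x[:, idx] + d * labels

    rng_inter = substream(spec.seed, "interactions")
    r = spec.interaction_magnitude_ratio
    # negative-class scale keeps the mixture variance at 1
    q = np.sqrt((1.0 - spec.prevalence * r**2) / (1.0 - spec.prevalence))
    scale = np.where(labels == 1, r, q)
    for i, j, strength in spec.interaction_effects:
        flip = (1.0 - strength) / 2.0
        mag_i = np.abs(rng_inter.standard_normal(spec.n_patients)) * scale
        mag_j = np.abs(rng_inter.standard_normal(spec.n_patients)) * scale
        sign_i = rng_inter.choice((-1.0, 1.0), size=spec.n_patients)
        # target product sign follows the class sign, flipped w.p. `flip`
        flips = rng_inter.random(spec.n_patients) < flip
        target = (2.0 * labels - 1.0) * np.where(flips, -1.0, 1.0)
        # overwrite the pair; any marginal nudge on a member is re-applied
        x[:, i] = sign_i * mag_i + _marginal_component(spec, i, labels)
        x[:, j] = sign_i * target * mag_j + _marginal_component(spec, j, labels)

    values = spec.noise_sd * x
    names = default_feature_names(spec.n_features)
    table = FeatureTable(
        patient_ids=[f"P{k:04d}" for k in range(spec.n_patients)],
        feature_names=names,
        values=values,
        labels=labels,
        provenance=f"synthetic cohort, seed={spec.seed}",
    )
    table.validate()
    manifest = {
        "seed": spec.seed,
        "n_patients": spec.n_patients,
        "n_positive": spec.n_positive,
        "marginal_effects": [
            {"feature": names[idx], "index": idx, "d": d}
            for idx, d in spec.marginal_effects
        ],
        "interaction_effects": [
            {
                "features": [names[i], names[j]],
                "indices": [i, j],
                "strength": s,
            }
            for i, j, s in spec.interaction_effects
        ],
        "blocks": [list(b) for b in spec.block_structure],
    }
    return table, manifest


def _marginal_component(spec: SyntheticSpec, idx: int, labels: np.ndarray) -> np.ndarray:
    """Standardized shift applied to feature ``idx``, if one was specified."""
    for k, d in spec.marginal_effects:
        if k == idx:
            return d * labels
    return np.zeros_like(labels, dtype=np.float64)


def generate_perturbed_replicates(
    table: FeatureTable, spec: SyntheticSpec
) -> list[FeatureTable]:
    """Replicate tables = original values + iid Gaussian measurement noise.

    Emulates perturbed re-measurements of the same patients for ICC
    robustness filtering; ids, columns and labels are untouched.
    """
    spec.validate()
    rng = substream(spec.seed, "replicates")
    out = []
    for r in range(spec.n_replicates):
        noise = rng.normal(0.0, 1.0, size=table.values.shape)
        rep = FeatureTable(
            list(table.patient_ids),
            list(table.feature_names),
            table.values + spec.replicate_noise_sd * noise,
            table.labels.copy(),
            provenance=f"{table.provenance} | replicate {r}",
        )
        out.append(rep)
    return out


def with_seed(spec: SyntheticSpec, seed: int) -> SyntheticSpec:
    return dataclasses.replace(spec, seed=seed)
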