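"""Robustness filtering, standardization and MI selection."""

import numpy as np
import pytest

from synolitic.cohort import FeatureTable, SyntheticSpec, generate_cohort, generate_perturbed_replicates
from synolitic.errors import ConfigurationError, StructuralError
from synolitic.preprocess import (
    FeatureRanking,
    compute_icc,
    icc_filter,
    mi_rank,
    select_top_n,
    zscore_apply,
    zscore_fit,
    zscore_invert,
)


def _table(values, labels=None, names=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return FeatureTable(
        [f"P{i}" for i in range(n)],
        names or [f"f{j}" for j in range(p)],
        values,
        labels if labels is not None else np.tile([0, 1], n)[:n],
    )


class TestICC:
    def test_identical_replicates_all_retained(self):
        rng = np.random.default_rng(0)
        t = _table(rng.standard_normal((30, 4)))
        reps = [t.copy(), t.copy()]
        assert icc_filter(t, reps, cutoff=0.8) == t.feature_names

    def test_independent_noise_dropped(self):
        rng = np.random.default_rng(1)
        t = _table(rng.standard_normal((200, 3)))
        reps = [_table(rng.standard_normal((200, 3)))]
        assert icc_filter(t, reps, cutoff=0.8) == []

    def test_cutoff_is_strict(self):
        # engineer a feature whose ICC estimate we then use as the cutoff
        rng = np.random.default_rng(2)
        base = rng.standard_normal(100)
        m = np.column_stack([base, base + rng.normal(0, 0.5, 100)])
        icc = compute_icc(m)
        t = _table(m[:, :1])
        reps = [_table(m[:, 1:])]
        assert icc_filter(t, reps, cutoff=icc) == []  # equality drops
        assert icc_filter(t, reps, cutoff=icc - 1e-9) == ["f0"]

    def test_icc_matches_variance_component_prediction(self):
        # ICC -> sigma_b^2 / (sigma_b^2 + sigma_e^2) for additive noise
        spec = SyntheticSpec(n_patients=800, n_features=4, block_structure=(),
                             n_replicates=3, replicate_noise_sd=0.5, seed=6)
        table, _ = generate_cohort(spec)
        reps = generate_perturbed_replicates(table, spec)
        stack = np.stack([table.values] + [r.values for r in reps], axis=2)
        expected = 1.0 / (1.0 + 0.5**2 / 1.0)  # between=1, noise=0.25 -> 0.8
        for j in range(4):
            icc = compute_icc(stack[:, j, :])
            assert abs(icc - expected) < 0.06

    def test_extreme_noise_levels(self):
        spec_low = SyntheticSpec(n_patients=300, n_features=3, block_structure=(),
                                 n_replicates=2, replicate_noise_sd=0.01, seed=8)
        t, _ = generate_cohort(spec_low)
        reps = generate_perturbed_replicates(t, spec_low)
        assert icc_filter(t, reps, cutoff=0.99) == t.feature_names
        spec_high = SyntheticSpec(n_patients=300, n_features=3, block_structure=(),
                                  n_replicates=2, replicate_noise_sd=10.0, seed=8)
        t2, _ = generate_cohort(spec_high)
        reps2 = generate_perturbed_replicates(t2, spec_high)
        stack = np.stack([t2.values] + [r.values for r in reps2], axis=2)
        assert all(compute_icc(stack[:, j, :]) < 0.1 for j in range(3))

    def test_replicate_order_invariance(self):
        spec = SyntheticSpec(n_patients=60, n_features=5, block_structure=(),
                             n_replicates=3, replicate_noise_sd=0.7, seed=3)
        t, _ = generate_cohort(spec)
        reps = generate_perturbed_replicates(t, spec)
        assert icc_filter(t, reps, 0.5) == icc_filter(t, reps[::-1], 0.5)

    def test_matches_independent_anova_oracle(self):
        # cross-check the variance-components formula against pingouin
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(5)
        m = rng.standard_normal((25, 1)) + 0.6 * rng.standard_normal((25, 3))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(25), 3),
                "rater": np.tile(np.arange(3), 25),
                "value": m.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(long, targets="subject", raters="rater",
                                       ratings="value")
        icc_a1 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert abs(compute_icc(m) - icc_a1) < 1e-6

    def test_structural_errors(self):
        t = _table(np.zeros((10, 2)) + np.arange(10)[:, None])
        other = _table(np.ones((10, 2)), names=["g0", "g1"])
        with pytest.raises(StructuralError):
            icc_filter(t, [other])
        with pytest.raises(ConfigurationError):
            icc_filter(t, [])


class TestZscore:
    def test_fit_and_transform_small_example(self):
        t = _table(np.array([[1.0], [2.0], [3.0]]), labels=np.array([0, 1, 0]))
        params = zscore_fit(t, [0, 1, 2])
        assert params.mean[0] == pytest.approx(2.0)
        assert params.sd[0] == pytest.approx(1.0)  # sample SD convention
        out = zscore_apply(t, params)
        assert out.values.mean() == pytest.approx(0.0)
        # a test row at the training mean maps to zero
        test = _table(np.array([[2.0]]), labels=np.array([1]))
        assert zscore_apply(test, params).values[0, 0] == pytest.approx(0.0)

    def test_round_trip(self, small_cohort):
        table, _, _ = small_cohort
        params = zscore_fit(table, np.arange(60))
        back = zscore_invert(zscore_apply(table, params), params)
        np.testing.assert_allclose(back.values, table.values, atol=1e-10)

    def test_fold_safety(self, small_cohort):
        table, _, _ = small_cohort
        rows = np.arange(60)
        params = zscore_fit(table, rows)
        mutated = table.copy()
        mutated.values[60:] += 100.0
        mutated.labels[60:] = 1 - mutated.labels[60:]
        params2 = zscore_fit(mutated, rows)
        np.testing.assert_array_equal(params.mean, params2.mean)
        np.testing.assert_array_equal(params.sd, params2.sd)

    def test_constant_column_rejected_by_name(self):
        t = _table(np.column_stack([np.ones(10), np.arange(10.0)]))
        with pytest.raises(ConfigurationError, match="f0"):
            zscore_fit(t, np.arange(10))


class TestMIRanking:
    def test_label_copy_feature_ranks_first(self):
        rng = np.random.default_rng(0)
        y = np.tile([0, 1], 50)
        values = np.column_stack([rng.standard_normal(100), y.astype(float),
                                  rng.standard_normal(100)])
        t = _table(values, labels=y)
        ranking = mi_rank(t, np.arange(100))
        assert ranking.names[0] == "f1"
        assert ranking.scores[0] > 0.3

    def test_stronger_shift_ranks_higher(self):
        wins = 0
        for seed in range(30):
            spec = SyntheticSpec(
                n_patients=343, prevalence=0.213, n_features=4, block_structure=(),
                marginal_effects=((0, 1.5), (1, 0.3)), seed=seed,
            )
            table, _ = generate_cohort(spec)
            ranking = mi_rank(table, np.arange(343), seed=seed)
            names = ranking.names
            if names.index(table.feature_names[0]) < names.index(table.feature_names[1]):
                wins += 1
        assert wins >= 28  # d=1.5 beats d=0.3 in >= ~95% of draws

    def test_deterministic_given_seed_and_tie_break(self):
        rng = np.random.default_rng(1)
        t = _table(rng.standard_normal((80, 6)))
        r1 = mi_rank(t, np.arange(80), seed=5)
        r2 = mi_rank(t, np.arange(80), seed=5)
        assert r1 == r2
        # all-zero scores sort lexicographically
        zero = FeatureRanking(tuple((n, 0.0) for n in ("b", "a", "c")))
        assert select_top_n(FeatureRanking(tuple(sorted(zero.entries))), 3) == ["a", "b", "c"]

    def test_single_class_rejected(self):
        t = _table(np.random.default_rng(0).standard_normal((20, 3)),
                   labels=np.zeros(20, dtype=int))
        with pytest.raises(ConfigurationError):
            mi_rank(t, np.arange(20))


class TestSelectTopN:
    def test_prefix_property_and_bounds(self):
        ranking = FeatureRanking(tuple((f"f{i}", 1.0 - i * 0.1) for i in range(8)))
        full = select_top_n(ranking, 8)
        assert full == ranking.names
        assert select_top_n(ranking, 1) == [ranking.names[0]]
        for a in range(1, 8):
            for b in range(a, 9):
                assert select_top_n(ranking, a) == select_top_n(ranking, b)[:a]
        with pytest.raises(ConfigurationError):
            select_top_n(ranking, 9)
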