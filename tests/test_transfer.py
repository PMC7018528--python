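import dataclasses
from itertools import permutations

import numpy as np
import pytest

from mbclock import (
    CohortConfig,
    ConfigurationError,
    generate_cohort,
    generate_multi_cohort,
    mean_absolute_error,
    permutation_null_mae,
    stratified_cross_train,
    tune_and_train,
)
from tests.conftest import QUICK_MODEL


@pytest.fixture(scope="module")
def trained_pair():
    """A small signal cohort split into train/test halves with a model."""
    table, meta = generate_cohort(
        CohortConfig(n_samples=160, n_features=80, n_young_markers=10,
                     n_old_markers=10, seed=60)
    )
    ages = meta["age"].to_numpy()
    train_tab = table.select_samples(table.sample_ids[:100])
    test_tab = table.select_samples(table.sample_ids[100:])
    model = tune_and_train(
        train_tab, ages[:100], dataclasses.replace(QUICK_MODEL, n_trees=60, seed=60)
    )
    return model, test_tab, ages[100:]


class TestPermutationNull:
    def test_strong_signal_hits_p_floor(self, trained_pair):
        model, test_tab, test_ages = trained_pair
        null = permutation_null_mae(model, test_tab, test_ages, n_perm=1000, seed=1)
        assert null.p_value == pytest.approx(1 / 1001)
        assert (null.null_maes > null.observed_mae).all()

    def test_constant_test_ages_give_p_one(self, trained_pair):
        model, test_tab, _ = trained_pair
        const = np.full(test_tab.n_samples, 50.0)
        null = permutation_null_mae(model, test_tab, const, n_perm=50, seed=2)
        assert null.p_value == 1.0
        np.testing.assert_allclose(null.null_maes, null.observed_mae)

    def test_p_never_zero_and_in_unit_interval(self, trained_pair):
        model, test_tab, test_ages = trained_pair
        null = permutation_null_mae(model, test_tab, test_ages, n_perm=5, seed=3)
        assert 0.0 < null.p_value <= 1.0

    def test_sampled_null_lies_on_enumerated_support(self, trained_pair):
        """For a tiny test set the permute-test null values must come from
        the finite set generated by all age permutations."""
        model, test_tab, test_ages = trained_pair
        small = test_tab.select_samples(test_tab.sample_ids[:5])
        ages5 = test_ages[:5]
        from mbclock import predict_microbiota_age

        preds = predict_microbiota_age(model, small).microbiota_age
        support = {
            round(mean_absolute_error(preds, np.array(p)), 9)
            for p in permutations(ages5)
        }
        null = permutation_null_mae(model, small, ages5, n_perm=100, seed=4)
        for value in null.null_maes:
            assert round(value, 9) in support

    def test_unknown_mode_rejected(self, trained_pair):
        model, test_tab, test_ages = trained_pair
        with pytest.raises(ConfigurationError):
            permutation_null_mae(model, test_tab, test_ages, n_perm=5, mode="bogus")

    def test_permute_train_needs_training_data(self, trained_pair):
        model, test_tab, test_ages = trained_pair
        with pytest.raises(ConfigurationError):
            permutation_null_mae(
                model, test_tab, test_ages, n_perm=2, mode="permute_train"
            )

    def test_permute_train_null_not_better_than_observed(self):
        table, meta = generate_cohort(
            CohortConfig(n_samples=80, n_features=40, n_young_markers=6,
                         n_old_markers=6, seed=61)
        )
        ages = meta["age"].to_numpy()
        config = dataclasses.replace(QUICK_MODEL, n_trees=30, cv_folds=3, seed=61)
        train_tab = table.select_samples(table.sample_ids[:50])
        test_tab = table.select_samples(table.sample_ids[50:])
        null = permutation_null_mae(
            (train_tab, ages[:50], config), test_tab, ages[50:],
            n_perm=5, mode="permute_train", seed=5,
        )
        assert null.p_value <= 1 / 3  # signal survives; shuffled training does not


@pytest.fixture(scope="module")
def two_cohorts():
    configs = [
        CohortConfig(n_samples=80, n_features=60, n_young_markers=8,
                     n_old_markers=8, cohort_label=label, seed=seed)
        for label, seed in (("A", 70), ("B", 71))
    ]
    return generate_multi_cohort(configs, shared_marker_fraction=1.0)


class TestCrossTrain:
    def test_matrix_shape_and_determinism(self, two_cohorts):
        table, meta = two_cohorts
        config = dataclasses.replace(QUICK_MODEL, n_trees=40, cv_folds=3, seed=70)
        r1 = stratified_cross_train(table, meta, "cohort", config)
        r2 = stratified_cross_train(table, meta, "cohort", config)
        assert r1.strata == ["A", "B"]
        assert r1.mae.shape == (2, 2)
        np.testing.assert_array_equal(r1.mae, r2.mae)

    def test_entries_invariant_to_stratum_listing_order(self, two_cohorts):
        """Relabelling a stratum so the sorted level order flips must not
        change any train/test entry."""
        table, meta = two_cohorts
        config = dataclasses.replace(QUICK_MODEL, n_trees=40, cv_folds=3, seed=70)
        r1 = stratified_cross_train(table, meta, "cohort", config)
        relabelled = meta.assign(cohort=meta["cohort"].map({"A": "Z", "B": "B"}))
        r2 = stratified_cross_train(table, relabelled, "cohort", config)
        assert r2.strata == ["B", "Z"]
        np.testing.assert_allclose(r2.mae, r1.mae[::-1, ::-1])

    def test_shared_markers_transfer_well(self, two_cohorts):
        table, meta = two_cohorts
        config = dataclasses.replace(QUICK_MODEL, n_trees=60, cv_folds=3, seed=70)
        result = stratified_cross_train(table, meta, "cohort", config)
        diag = np.diag(result.mae)
        off = result.mae[~np.eye(2, dtype=bool)]
        assert (off <= 1.5 * diag.max()).all()

    def test_single_stratum_rejected(self, two_cohorts):
        table, meta = two_cohorts
        only_a = meta[meta["cohort"] == "A"]
        with pytest.raises(ConfigurationError):
            stratified_cross_train(
                table.select_samples(only_a["sample_id"].tolist()),
                only_a, "cohort", QUICK_MODEL,
            )

    def test_small_stratum_error_names_level(self, two_cohorts):
        table, meta = two_cohorts
        meta = meta.copy()
        meta.loc[meta.index[:3], "cohort"] = "tiny"
        with pytest.raises(ConfigurationError, match="tiny"):
            stratified_cross_train(table, meta, "cohort", QUICK_MODEL)
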