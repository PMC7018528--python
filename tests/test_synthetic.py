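import numpy as np
import pytest
from scipy.stats import spearmanr

from mbclock import (
    AgeDistribution,
    CohortConfig,
    ConfigurationError,
    abundance_ubiquity_summary,
    generate_accelerated_group,
    generate_cohort,
    generate_multi_cohort,
    marker_directions,
    marker_ids,
)


def test_same_seed_gives_bitwise_identical_tables():
    cfg = CohortConfig(n_samples=50, n_features=40, n_young_markers=5,
                       n_old_markers=5, seed=11)
    t1, m1 = generate_cohort(cfg)
    t2, m2 = generate_cohort(cfg)
    assert np.array_equal(t1.values, t2.values)
    assert t1.sample_ids == t2.sample_ids
    assert m1.equals(m2)


def test_rows_are_compositionally_closed(default_cohort):
    table, _ = default_cohort
    np.testing.assert_allclose(table.values.sum(axis=1), 1.0, atol=1e-9)
    assert (table.values >= 0).all()


def test_marker_counts_exceeding_features_rejected():
    with pytest.raises(ConfigurationError):
        CohortConfig(n_features=10, n_young_markers=8, n_old_markers=8)


def test_age_bounds_outside_adult_range_rejected():
    with pytest.raises(ConfigurationError):
        AgeDistribution(min_age=10.0)


def _group_summaries(table):
    directions = marker_directions(table.feature_ids)
    young = [f for f, d in directions.items() if d == "young_enriched"]
    old = [f for f, d in directions.items() if d == "old_enriched"]
    return (
        abundance_ubiquity_summary(table, young),
        abundance_ubiquity_summary(table, old),
    )


def test_young_markers_more_prevalent_and_abundant_than_old():
    table, _ = generate_cohort(CohortConfig(n_young_markers=10, n_old_markers=10, seed=2))
    young, old = _group_summaries(table)
    assert np.mean([s.ubiquity for s in young]) > np.mean([s.ubiquity for s in old])
    assert np.mean([s.mean_relative_abundance for s in young]) > np.mean(
        [s.mean_relative_abundance for s in old]
    )


def test_young_marker_monotone_decline_without_noise():
    table, meta = generate_cohort(
        CohortConfig(n_samples=80, n_features=60, n_young_markers=8,
                     n_old_markers=8, noise_sd=0.0, seed=3)
    )
    order = np.argsort(meta["age"].to_numpy())
    directions = marker_directions(table.feature_ids)
    for j, f in enumerate(table.feature_ids):
        if directions.get(f) == "young_enriched":
            col = table.values[order, j]
            assert (np.diff(col) <= 1e-12).all(), f"{f} not non-increasing in age"


def test_no_signal_spearman_calibration():
    """With effect_size=0 the fraction of nominally significant age
    correlations stays near the 5% type-I level across replicates."""
    frac_significant = []
    for seed in range(20):
        table, meta = generate_cohort(
            CohortConfig(n_samples=100, n_features=60, n_young_markers=8,
                         n_old_markers=8, effect_size=0.0, seed=seed)
        )
        ages = meta["age"].to_numpy()
        pvals = np.array(
            [spearmanr(table.values[:, j], ages).pvalue for j in range(table.n_features)]
        )
        frac_significant.append(np.mean(pvals < 0.05))
    assert np.mean(frac_significant) < 0.10


def test_skewed_age_distribution_is_right_skewed_and_bounded():
    cfg = CohortConfig(
        n_samples=400, age_distribution=AgeDistribution(kind="skewed"), seed=4
    )
    _, meta = generate_cohort(cfg)
    ages = meta["age"].to_numpy()
    assert ages.min() >= 18.0 and ages.max() <= 90.0
    assert np.median(ages) < ages.mean()  # right skew
    assert (ages < 40).mean() > 0.6  # young-heavy


def test_violation_fraction_populates_exclusion_flags():
    _, meta = generate_cohort(CohortConfig(n_samples=400, violation_fraction=0.2, seed=5))
    for col in ("ibd", "pregnant", "hospitalized"):
        assert 0.05 < meta[col].mean() < 0.4
    assert (meta["bmi"] > 30).mean() > 0.05


class TestMultiCohort:
    def _configs(self, n_markers=10):
        return [
            CohortConfig(n_samples=40, n_features=60, n_young_markers=n_markers // 2,
                         n_old_markers=n_markers // 2, cohort_label=label, seed=seed)
            for label, seed in (("A", 20), ("B", 21))
        ]

    def test_all_shared_means_no_zero_markers_within_cohorts(self):
        table, meta = generate_multi_cohort(self._configs(), shared_marker_fraction=1.0)
        for label in ("A", "B"):
            rows = (meta["cohort"] == label).to_numpy()
            for j, f in enumerate(table.feature_ids):
                if f in marker_directions(table.feature_ids):
                    assert table.values[rows, j].sum() > 0, (label, f)

    def test_disjoint_markers_zero_in_other_cohort(self):
        table, meta = generate_multi_cohort(self._configs(), shared_marker_fraction=0.0)
        rows_b = (meta["cohort"] == "B").to_numpy()
        a_markers = [f for f in marker_ids(table.feature_ids) if "_A_" in f]
        assert a_markers
        for f in a_markers:
            j = table.feature_ids.index(f)
            assert (table.values[rows_b, j] == 0).all()

    def test_half_shared_gives_exact_shared_count(self):
        table, _ = generate_multi_cohort(self._configs(n_markers=20),
                                         shared_marker_fraction=0.5)
        shared = [
            f for f in marker_ids(table.feature_ids)
            if "_A_" not in f and "_B_" not in f
        ]
        assert len(shared) == 10

    def test_empty_config_list_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_multi_cohort([], shared_marker_fraction=0.5)


class TestAcceleratedGroup:
    def test_zero_accel_is_plain_cohort(self):
        cfg = CohortConfig(n_samples=60, n_features=50, n_young_markers=6,
                           n_old_markers=6, seed=30)
        plain_table, plain_meta = generate_cohort(cfg)
        table, meta = generate_accelerated_group(cfg, n_accel=0, age_offset=5.0)
        assert np.array_equal(table.values, plain_table.values)
        assert (meta["group"] == "control").all()
        assert meta.drop(columns="group").equals(plain_meta)

    def test_group_sizes_and_flagging(self):
        cfg = CohortConfig(n_samples=60, n_features=50, n_young_markers=6,
                           n_old_markers=6, seed=31)
        table, meta = generate_accelerated_group(cfg, n_accel=15, age_offset=10.0)
        assert table.n_samples == 75
        assert (meta["group"] == "accelerated").sum() == 15
        np.testing.assert_allclose(table.values.sum(axis=1), 1.0, atol=1e-9)

    def test_negative_offset_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_accelerated_group(CohortConfig(), n_accel=5, age_offset=-1.0)
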