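"""Synthetic age-structured, compositional cohorts.

The generator emulates the statistical structure that microbiome ageing
analyses rely on, without simulating sequences:

* per-ASV log-normal baseline abundances;
* marker ASVs whose log-abundance changes linearly with host age —
  young-enriched markers start from a high baseline and decline, old-enriched
  markers start from a very low baseline and rise;
* a detection floor that zeroes raw abundances below a threshold before
  compositional closure, which is what makes old-enriched markers sparse
  (low ubiquity) while young-enriched markers remain ubiquitous;
* optional cohort-private markers (zero outside their cohort), a
  female-restricted marker subset, and right-skewed age distributions.

Feature identifiers encode ground truth (``ASV_young_*``, ``ASV_old_*``,
``ASV_bg_*``) so downstream evaluations can recover the marker list without
a side channel.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .tables import FeatureTable

__all__ = [
    "AgeDistribution",
    "CohortConfig",
    "generate_cohort",
    "generate_multi_cohort",
    "generate_accelerated_group",
    "marker_ids",
    "marker_directions",
]

AGE_MIN, AGE_MAX = 18.0, 90.0
#: age at which a marker sits exactly on its baseline log-abundance
AGE_CENTER = 54.0

# log-scale baseline means: young markers are abundant, old markers are rare,
# background ASVs sit in between.  The detection floor (on the raw, pre-closure
# scale) turns the low old-marker baseline into sparsity.  The background is
# heavy-tailed (sd 2) so that, as in real communities, a handful of dominant
# taxa carry most of each sample's mass; this keeps the closure denominator
# noise-dominated rather than marker-dominated, so compositional closure does
# not smear marker age trends onto non-marker features.
_BG_LOG_MEAN, _BG_LOG_SD = -2.0, 2.0
_YOUNG_LOG_MEAN, _YOUNG_LOG_SD = -2.0, 0.5
_OLD_LOG_MEAN, _OLD_LOG_SD = -6.0, 0.5


@dataclass(frozen=True)
class AgeDistribution:
    """Host age distribution: uniform on [min, max] or right-skewed.

    ``skewed`` draws ``min_age + Gamma(shape, scale=5)`` truncated to
    ``[min_age, max_age]`` by resampling, giving the young-heavy age
    histograms typical of crowdsourced cohorts.
    """

    kind: str = "uniform"  # uniform | skewed
    min_age: float = AGE_MIN
    max_age: float = AGE_MAX
    shape: float = 3.0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "skewed"):
            raise ConfigurationError(f"unknown age distribution kind: {self.kind!r}")
        if not (AGE_MIN <= self.min_age < self.max_age <= AGE_MAX):
            raise ConfigurationError(
                f"age bounds [{self.min_age}, {self.max_age}] must lie within "
                f"[{AGE_MIN:.0f}, {AGE_MAX:.0f}]"
            )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "uniform":
            return rng.uniform(self.min_age, self.max_age, size=n)
        ages = np.empty(n)
        filled = 0
        while filled < n:
            draw = self.min_age + rng.gamma(self.shape, 5.0, size=n)
            ok = draw[draw <= self.max_age]
            take = min(ok.size, n - filled)
            ages[filled : filled + take] = ok[:take]
            filled += take
        return ages


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic cohort.

    ``effect_size`` is the absolute slope of marker log-abundance per year of
    host age (young markers get ``-effect_size``, old markers
    ``+effect_size``).  ``noise_sd`` is the log-scale dispersion added per
    sample and feature.  ``detection_floor`` is on the raw (pre-closure)
    abundance scale.  ``violation_fraction`` is the probability that a sample
    violates each exclusion criterion (BMI range and the six health/status
    flags), used to exercise metadata filtering.
    """

    n_samples: int = 500
    n_features: int = 200
    n_young_markers: int = 25
    n_old_markers: int = 25
    effect_size: float = 0.05
    cohort_label: str = "cohortA"
    cohort_specific_fraction: float = 0.0
    sex_effect: bool = False
    sex_specific_fraction: float = 0.5
    age_distribution: AgeDistribution = field(default_factory=AgeDistribution)
    noise_sd: float = 1.0
    detection_floor: float = float(np.exp(-5.0))
    violation_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_young_markers + self.n_old_markers > self.n_features:
            raise ConfigurationError(
                f"{self.n_young_markers} + {self.n_old_markers} markers exceed "
                f"{self.n_features} features"
            )
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be >= 0")
        if not 0.0 <= self.cohort_specific_fraction <= 1.0:
            raise ConfigurationError("cohort_specific_fraction must be in [0, 1]")
        if not 0.0 <= self.violation_fraction <= 1.0:
            raise ConfigurationError("violation_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.n_samples < 1 or self.n_features < 1:
            raise ConfigurationError("n_samples and n_features must be positive")


def marker_directions(feature_ids: Sequence[str]) -> dict[str, str]:
    """Map each marker feature id to its direction; background ids omitted."""
    out = {}
    for f in feature_ids:
        if f.startswith("ASV_young"):
            out[f] = "young_enriched"
        elif f.startswith("ASV_old"):
            out[f] = "old_enriched"
    return out


def marker_ids(feature_ids: Sequence[str]) -> list[str]:
    """All marker (non-background) feature ids, in table order."""
    return [f for f in feature_ids if not f.startswith("ASV_bg")]


def _feature_ids(config: CohortConfig, private_label: str | None = None) -> list[str]:
    tag = f"{private_label}_" if private_label else ""
    young = [f"ASV_young_{tag}{i:04d}" for i in range(config.n_young_markers)]
    old = [f"ASV_old_{tag}{i:04d}" for i in range(config.n_old_markers)]
    n_bg = config.n_features - config.n_young_markers - config.n_old_markers
    bg = [f"ASV_bg_{i:04d}" for i in range(n_bg)]
    return young + old + bg


def _baselines(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    n_bg = config.n_features - config.n_young_markers - config.n_old_markers
    return np.concatenate(
        [
            rng.normal(_YOUNG_LOG_MEAN, _YOUNG_LOG_SD, config.n_young_markers),
            rng.normal(_OLD_LOG_MEAN, _OLD_LOG_SD, config.n_old_markers),
            rng.normal(_BG_LOG_MEAN, _BG_LOG_SD, n_bg),
        ]
    )


def _slopes(config: CohortConfig) -> np.ndarray:
    s = np.zeros(config.n_features)
    s[: config.n_young_markers] = -config.effect_size
    s[config.n_young_markers : config.n_young_markers + config.n_old_markers] = (
        config.effect_size
    )
    return s


def _metadata_frame(
    config: CohortConfig,
    sample_ids: list[str],
    ages: np.ndarray,
    sexes: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = len(sample_ids)
    v = config.violation_fraction
    bmi = np.clip(rng.normal(24.0, 2.5, n), 18.5, 30.0)
    if v > 0:
        out_of_range = rng.random(n) < v
        bmi = np.where(out_of_range, rng.uniform(30.5, 45.0, n), bmi)
    flags = {
        name: (rng.random(n) < v) if v > 0 else np.zeros(n, dtype=bool)
        for name in (
            "ibd",
            "diabetes",
            "antibiotics_past_month",
            "pregnant",
            "hospitalized",
            "disabled",
            "critically_ill",
        )
    }
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age": ages,
            "sex": sexes,
            "bmi": bmi,
            "country": config.cohort_label,
            "body_site": "gut",
            "body_subsite": "feces",
            "cohort": config.cohort_label,
            **{k: f.astype(bool) for k, f in flags.items()},
        }
    )


def _abundance_matrix(
    config: CohortConfig,
    baselines: np.ndarray,
    eff_ages: np.ndarray,
    sexes: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Raw abundances -> detection floor -> compositional closure."""
    slopes = _slopes(config)
    slope_matrix = np.broadcast_to(slopes, (len(eff_ages), config.n_features)).copy()
    if config.sex_effect:
        # a leading subset of each marker block carries signal in females only
        n_sy = int(round(config.sex_specific_fraction * config.n_young_markers))
        n_so = int(round(config.sex_specific_fraction * config.n_old_markers))
        female_only = np.zeros(config.n_features, dtype=bool)
        female_only[:n_sy] = True
        female_only[config.n_young_markers : config.n_young_markers + n_so] = True
        male = sexes == "male"
        slope_matrix[np.ix_(male, female_only)] = 0.0
    log_ab = (
        baselines[None, :]
        + slope_matrix * (eff_ages[:, None] - AGE_CENTER)
        + (rng.normal(0.0, config.noise_sd, (len(eff_ages), config.n_features))
           if config.noise_sd > 0 else 0.0)
    )
    raw = np.exp(log_ab)
    raw[raw < config.detection_floor] = 0.0
    sums = raw.sum(axis=1)
    sums[sums == 0] = 1.0  # degenerate all-zero row stays all-zero
    return raw / sums[:, None]


def _generate(
    config: CohortConfig,
    private_label: str | None = None,
    shared_young: int | None = None,
    shared_old: int | None = None,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Single-cohort draw.  When ``shared_young``/``shared_old`` are given,
    only the first that-many markers per block keep shared (cohort-agnostic)
    ids; the rest get cohort-private ids."""
    rng = np.random.default_rng(config.seed)
    baselines = _baselines(config, rng)
    ages = config.age_distribution.sample(config.n_samples, rng)
    sexes = np.where(rng.random(config.n_samples) < 0.5, "female", "male")
    sample_ids = [f"{config.cohort_label}_s{i:04d}" for i in range(config.n_samples)]
    metadata = _metadata_frame(config, sample_ids, ages, sexes, rng)
    values = _abundance_matrix(config, baselines, ages, sexes, rng)

    ids = _feature_ids(config)
    if private_label is not None:
        sy = config.n_young_markers if shared_young is None else shared_young
        so = config.n_old_markers if shared_old is None else shared_old
        private = _feature_ids(config, private_label)
        ids = (
            ids[:sy]
            + private[sy : config.n_young_markers]
            + ids[config.n_young_markers : config.n_young_markers + so]
            + private[config.n_young_markers + so : config.n_young_markers + config.n_old_markers]
            + ids[config.n_young_markers + config.n_old_markers :]
        )
    return FeatureTable(sample_ids, ids, values), metadata


def generate_cohort(config: CohortConfig) -> tuple[FeatureTable, pd.DataFrame]:
    """Generate one cohort: a closed feature table plus host metadata.

    Deterministic given ``config.seed``.  Rows sum to one unless every
    feature of a sample fell below the detection floor (practically
    impossible under default parameters).
    """
    return _generate(config)


def generate_multi_cohort(
    configs: Sequence[CohortConfig], shared_marker_fraction: float | None = None
) -> tuple[FeatureTable, pd.DataFrame]:
    """Concatenate cohorts that share a fraction of their marker ASVs.

    The stated fraction of each cohort's young and old markers keep ids
    common to all cohorts (and carry age signal everywhere); the remainder
    get cohort-private ids and are exactly zero outside their own cohort.
    Background ASVs are shared.  The combined table spans the union of
    feature ids.
    """
    if not configs:
        raise ConfigurationError("generate_multi_cohort needs at least one config")
    if shared_marker_fraction is None:
        shared_marker_fraction = 1.0 - configs[0].cohort_specific_fraction
    if not 0.0 <= shared_marker_fraction <= 1.0:
        raise ConfigurationError("shared_marker_fraction must be in [0, 1]")
    labels = [c.cohort_label for c in configs]
    if len(set(labels)) != len(labels):
        raise ConfigurationError("cohort labels must be unique")

    frames = []
    metas = []
    for cfg in configs:
        sy = int(round(shared_marker_fraction * cfg.n_young_markers))
        so = int(round(shared_marker_fraction * cfg.n_old_markers))
        table, meta = _generate(
            cfg, private_label=cfg.cohort_label, shared_young=sy, shared_old=so
        )
        frames.append(table.to_dataframe())
        metas.append(meta)

    # union of features, deterministic order: first-seen across cohorts
    all_ids: list[str] = []
    seen: set[str] = set()
    for df in frames:
        for f in df.columns:
            if f not in seen:
                seen.add(f)
                all_ids.append(f)
    combined = pd.concat(
        [df.reindex(columns=all_ids, fill_value=0.0) for df in frames], axis=0
    )
    metadata = pd.concat(metas, ignore_index=True)
    return FeatureTable.from_dataframe(combined), metadata


def generate_accelerated_group(
    config: CohortConfig, n_accel: int, age_offset: float
) -> tuple[FeatureTable, pd.DataFrame]:
    """Controls plus a group whose microbiome reflects an older age.

    Control samples are generated exactly as :func:`generate_cohort` would
    (same seed, same draws).  The ``n_accel`` accelerated samples use an
    independent stream derived from the seed; their marker slopes are
    evaluated at ``age + age_offset`` while their recorded chronological age
    is unchanged.  Metadata gains a ``group`` column (control/accelerated).
    """
    if age_offset < 0:
        raise ConfigurationError("age_offset must be >= 0")
    if n_accel < 0:
        raise ConfigurationError("n_accel must be >= 0")
    table, metadata = _generate(config)
    metadata = metadata.assign(group="control")
    if n_accel == 0:
        return table, metadata

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 104729]))
    # reuse the control cohort's per-feature baselines (same ASVs)
    baselines = _baselines(config, np.random.default_rng(config.seed))
    ages = config.age_distribution.sample(n_accel, rng)
    sexes = np.where(rng.random(n_accel) < 0.5, "female", "male")
    sample_ids = [f"{config.cohort_label}_a{i:04d}" for i in range(n_accel)]
    accel_meta = _metadata_frame(config, sample_ids, ages, sexes, rng)
    accel_meta = accel_meta.assign(group="accelerated")
    values = _abundance_matrix(config, baselines, ages + age_offset, sexes, rng)

    full = FeatureTable(
        table.sample_ids + sample_ids,
        list(table.feature_ids),
        np.vstack([table.values, values]),
    )
    return full, pd.concat([metadata, accel_meta], ignore_index=True)
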