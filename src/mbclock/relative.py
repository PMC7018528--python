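"""Relative microbiota age: spline reference trend and group comparison.

A cubic smoothing spline maps chronological age to the expected microbiota
age of the healthy reference population.  A sample's relative microbiota age
is its microbiota age minus that expectation at its own chronological age:
positive values mean an older-looking microbiome.  Groups of relative ages
are compared with the two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline, make_smoothing_spline
from scipy.stats import mannwhitneyu

from .exceptions import ConfigurationError, ConsistencyError

__all__ = [
    "SplineFit",
    "RelativeAgeResult",
    "fit_age_spline",
    "relative_microbiota_age",
    "compare_groups_wilcoxon",
]

_AGE_BOUNDS = (18.0, 90.0)


@dataclass
class SplineFit:
    """A fitted chronological-age -> expected-microbiota-age trend.

    Evaluation outside the fitting domain is clamped to the nearest boundary
    (smoothing splines extrapolate linearly and unreliably); a warning is
    emitted when clamping occurs.
    """

    spline: BSpline
    domain: tuple[float, float]
    smoothing: float | None  # None = generalized cross-validation

    def __call__(self, ages: Sequence[float] | float) -> np.ndarray:
        a = np.atleast_1d(np.asarray(ages, dtype=float))
        lo, hi = self.domain
        if (a < lo).any() or (a > hi).any():
            warnings.warn(
                f"ages outside the spline fitting domain [{lo:.1f}, {hi:.1f}] "
                "were clamped to the boundary",
                stacklevel=2,
            )
        return np.asarray(self.spline(np.clip(a, lo, hi)), dtype=float)


def fit_age_spline(
    chronological: Sequence[float],
    microbiota_age: Sequence[float],
    smoothing: float | None = None,
) -> SplineFit:
    """Fit a cubic smoothing spline of microbiota age on chronological age.

    ``smoothing`` is the roughness-penalty weight (lambda); when omitted it
    is chosen by generalized cross-validation.  Observations sharing a
    chronological age are merged into a weighted mean before fitting, which
    leaves the penalized least-squares solution unchanged.
    """
    x = np.asarray(chronological, dtype=float)
    y = np.asarray(microbiota_age, dtype=float)
    if x.shape != y.shape:
        raise ConsistencyError("chronological and microbiota ages differ in length")
    if x.size < 10:
        raise ConfigurationError("need at least 10 paired observations to fit the spline")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ConfigurationError("ages must be finite")
    if (x < _AGE_BOUNDS[0]).any() or (x > _AGE_BOUNDS[1]).any():
        raise ConfigurationError(
            f"chronological ages must lie within [{_AGE_BOUNDS[0]:.0f}, {_AGE_BOUNDS[1]:.0f}]"
        )
    ux, inverse, counts = np.unique(x, return_inverse=True, return_counts=True)
    if ux.size == 1:
        raise ConfigurationError("all chronological ages identical; spline undefined")
    if ux.size < 5:
        raise ConfigurationError(
            "need at least 5 distinct chronological ages for a cubic smoothing spline"
        )
    uy = np.bincount(inverse, weights=y) / counts
    spline = make_smoothing_spline(ux, uy, w=counts.astype(float), lam=smoothing)
    return SplineFit(spline=spline, domain=(float(ux[0]), float(ux[-1])), smoothing=smoothing)


@dataclass
class RelativeAgeResult:
    sample_ids: list[str]
    relative_age: np.ndarray
    chronological_age: np.ndarray
    microbiota_age: np.ndarray
    groups: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {
            "sample_id": self.sample_ids,
            "chronological_age": self.chronological_age,
            "microbiota_age": self.microbiota_age,
            "relative_age": self.relative_age,
        }
        if self.groups is not None:
            data["group"] = self.groups
        return pd.DataFrame(data)


def relative_microbiota_age(
    spline: SplineFit,
    chronological: Sequence[float],
    microbiota_age: Sequence[float],
    sample_ids: Sequence[str] | None = None,
    groups: Sequence[str] | None = None,
) -> RelativeAgeResult:
    """Signed deviation of each sample from the reference age trend (years)."""
    chron = np.asarray(chronological, dtype=float)
    micro = np.asarray(microbiota_age, dtype=float)
    if chron.shape != micro.shape:
        raise ConsistencyError("chronological and microbiota ages differ in length")
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(chron.size)]
    rel = micro - spline(chron)
    return RelativeAgeResult(
        sample_ids=list(sample_ids),
        relative_age=rel,
        chronological_age=chron,
        microbiota_age=micro,
        groups=None if groups is None else list(groups),
    )


def compare_groups_wilcoxon(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test between two groups of relative ages.

    Returns the Mann-Whitney U statistic of ``group_a`` and the p-value.
    The exact null distribution is used for small tie-free samples
    (n_a * n_b <= 400); otherwise the normal approximation with continuity
    correction and mid-ranks for ties.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ConfigurationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size * b.size <= 400 and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)
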