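"""Healthy-adult inclusion/exclusion filtering with per-criterion attrition.

A sample is retained only if its self-reported age is in [18, 90] years, its
BMI is in [18.5, 30] kg/m2 (both intervals closed), all health/status flags
are false (IBD, diabetes, antibiotics in the past month, pregnant,
hospitalized, disabled, critically ill), and no criterion column is missing.

Each removed sample is counted under the FIRST criterion it definitively
fails, in a fixed order (age, BMI, diseases, antibiotics, status flags);
samples whose only problem is a missing value fall through to the
``missing_values`` counter.  This makes the counters deterministic and
conserving: retained + removed = input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .exceptions import ConsistencyError, SchemaError
from .tables import FeatureTable

__all__ = ["FilterReport", "CRITERIA", "apply_inclusion_criteria", "filter_feature_table"]

AGE_RANGE = (18.0, 90.0)
BMI_RANGE = (18.5, 30.0)

#: criterion evaluation order; missing_values is always assessed last
CRITERIA = (
    "age_range",
    "bmi_range",
    "ibd",
    "diabetes",
    "antibiotics",
    "pregnant",
    "hospitalized",
    "disabled",
    "critically_ill",
    "missing_values",
)

_FLAG_COLUMNS = {
    "ibd": "ibd",
    "diabetes": "diabetes",
    "antibiotics": "antibiotics_past_month",
    "pregnant": "pregnant",
    "hospitalized": "hospitalized",
    "disabled": "disabled",
    "critically_ill": "critically_ill",
}

_REQUIRED = ("sample_id", "age", "bmi") + tuple(_FLAG_COLUMNS.values())


@dataclass
class FilterReport:
    """Attrition accounting for one filtering pass."""

    n_input: int
    removed: dict[str, int] = field(default_factory=dict)
    n_retained: int = 0
    retained_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "removed": dict(self.removed),
            "n_retained": self.n_retained,
            "retained_ids": list(self.retained_ids),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def summary(self) -> str:
        lines = [f"input samples: {self.n_input}"]
        for crit in CRITERIA:
            lines.append(f"  removed ({crit}): {self.removed.get(crit, 0)}")
        lines.append(f"retained: {self.n_retained}")
        return "\n".join(lines)


def _is_missing(value) -> bool:
    return pd.isna(value)


def _truthy(value) -> bool:
    """Interpret a metadata flag; accepts bools and common string encodings."""
    if isinstance(value, str):
        return value.strip().lower() in ("true", "yes", "y", "1", "t")
    return bool(value)


def _first_failure(row: pd.Series) -> str | None:
    """First criterion the row definitively fails, else None (retained).

    A missing value never triggers a range/flag criterion directly; if the
    row fails nothing on its present values but has any missing criterion
    value, it is attributed to ``missing_values``.
    """
    age, bmi = row["age"], row["bmi"]
    if not _is_missing(age) and not AGE_RANGE[0] <= float(age) <= AGE_RANGE[1]:
        return "age_range"
    if not _is_missing(bmi) and not BMI_RANGE[0] <= float(bmi) <= BMI_RANGE[1]:
        return "bmi_range"
    for crit, col in _FLAG_COLUMNS.items():
        if not _is_missing(row[col]) and _truthy(row[col]):
            return crit
    if _is_missing(age) or _is_missing(bmi):
        return "missing_values"
    for col in _FLAG_COLUMNS.values():
        if _is_missing(row[col]):
            return "missing_values"
    return None


def apply_inclusion_criteria(metadata: pd.DataFrame) -> FilterReport:
    """Evaluate the healthy-adult criteria on every sample.

    Raises :class:`SchemaError` naming the first required column that is
    absent from the metadata.
    """
    for col in _REQUIRED:
        if col not in metadata.columns:
            raise SchemaError(f"metadata lacks required column: {col!r}")
    report = FilterReport(n_input=len(metadata), removed={c: 0 for c in CRITERIA})
    for _, row in metadata.iterrows():
        failure = _first_failure(row)
        if failure is None:
            report.retained_ids.append(str(row["sample_id"]))
        else:
            report.removed[failure] += 1
    report.n_retained = len(report.retained_ids)
    return report


def filter_feature_table(table: FeatureTable, report: FilterReport) -> FeatureTable:
    """Subset the table to the report's retained samples, in report order.

    Values are passed through unchanged (no renormalization): the retained
    rows were closed over the full feature set and keep that interpretation.
    """
    missing = set(report.retained_ids) - set(table.sample_ids)
    if missing:
        raise ConsistencyError(
            f"retained sample id not present in feature table: {sorted(missing)[0]!r}"
        )
    return table.select_samples(report.retained_ids)
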