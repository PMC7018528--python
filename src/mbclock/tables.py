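"""ASV feature tables: containers, I/O, normalization, alignment, summaries.

The in-memory layout is samples x features.  On disk the TSV convention is
features x samples (rows are ASVs, columns are samples), which is how QIIME
and most amplicon pipelines export dense tables; orientation is converted on
read/write.  A dense BIOM 1.0 JSON writer/reader is provided for
interoperability with BIOM-consuming tools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConsistencyError, FormatError, SchemaError

__all__ = [
    "FeatureTable",
    "MarkerSummary",
    "read_table",
    "write_table",
    "read_metadata",
    "write_metadata",
    "to_relative_abundance",
    "align_features",
    "abundance_ubiquity_summary",
    "subsample_balance",
]

#: Required columns for a host metadata table.
METADATA_COLUMNS = (
    "sample_id",
    "age",
    "sex",
    "bmi",
    "country",
    "body_site",
    "body_subsite",
    "ibd",
    "diabetes",
    "antibiotics_past_month",
    "pregnant",
    "hospitalized",
    "disabled",
    "critically_ill",
)


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {kind} id: {i!r}")
        seen.add(i)


@dataclass
class FeatureTable:
    """A samples x features matrix of (relative) abundances.

    Attributes
    ----------
    sample_ids : list of str
        Row labels, unique.
    feature_ids : list of str
        Column labels (ASV identifiers), unique.
    values : ndarray of shape (n_samples, n_features)
        Nonnegative abundances.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("values must be a 2-D matrix")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ConsistencyError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("feature table contains non-finite values")
        if (self.values < 0).any():
            raise FormatError("feature table contains negative values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_dataframe(self) -> pd.DataFrame:
        """Samples x features DataFrame."""
        return pd.DataFrame(
            self.values.copy(), index=list(self.sample_ids), columns=list(self.feature_ids)
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        return cls(list(map(str, df.index)), list(map(str, df.columns)), df.to_numpy(dtype=float))

    def select_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        """Subset (and reorder) samples; raises on unknown ids."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [index[str(s)] for s in sample_ids]
        except KeyError as exc:
            raise ConsistencyError(f"sample id not in table: {exc.args[0]!r}") from None
        return FeatureTable(list(sample_ids), list(self.feature_ids), self.values[rows])

    def copy(self) -> "FeatureTable":
        return FeatureTable(list(self.sample_ids), list(self.feature_ids), self.values.copy())


@dataclass(frozen=True)
class MarkerSummary:
    """Mean relative abundance and ubiquity of one ASV across samples."""

    feature_id: str
    mean_relative_abundance: float
    ubiquity: float
    direction: str = "none"  # young_enriched | old_enriched | none


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_BIOM_FORMAT = "Biological Observation Matrix 1.0.0"


def write_table(table: FeatureTable, path: str | Path, format: str = "tsv") -> None:
    """Write a feature table as TSV (features x samples) or dense BIOM JSON."""
    path = Path(path)
    if format == "tsv":
        df = table.to_dataframe().T  # features x samples on disk
        df.index.name = "feature_id"
        df.to_csv(path, sep="\t")
    elif format == "biom_dense":
        doc = {
            "id": None,
            "format": _BIOM_FORMAT,
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "mbclock",
            "date": "",
            "matrix_type": "dense",
            "matrix_element_type": "float",
            "shape": [table.n_features, table.n_samples],
            "rows": [{"id": f, "metadata": None} for f in table.feature_ids],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": table.values.T.tolist(),
        }
        path.write_text(json.dumps(doc))
    else:
        raise FormatError(f"unknown table format: {format!r}")


def read_table(path: str | Path, format: str = "tsv") -> FeatureTable:
    """Read a feature table written by :func:`write_table`.

    TSV is features x samples (first column = feature ids, header = sample
    ids) and transposed on read.  ``biom_dense`` reads BIOM 1.0 JSON with a
    dense matrix.
    """
    path = Path(path)
    if format == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        seen: set[str] = set()
        for sid in header:
            if sid in seen:
                raise FormatError(f"duplicate sample id: {sid!r}")
            seen.add(sid)
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # ragged rows, empty file, ...
            raise FormatError(f"cannot parse {path} as TSV feature table: {exc}") from exc
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicate feature id: {dup!r}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError(f"non-numeric entries in {path}")
        return FeatureTable(list(map(str, df.columns)), list(map(str, df.index)), values.T)
    if format == "biom_dense":
        doc = json.loads(Path(path).read_text())
        if doc.get("matrix_type") != "dense":
            raise FormatError("only dense BIOM matrices are supported")
        feature_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        values = np.asarray(doc["data"], dtype=float).T
        return FeatureTable(sample_ids, feature_ids, values)
    raise FormatError(f"unknown table format: {format!r}")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a host metadata TSV, with ``sample_id`` as a column."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise SchemaError("metadata file lacks a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicate sample id: {dup!r}")
    return df


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def to_relative_abundance(table: FeatureTable) -> FeatureTable:
    """Close each sample to unit sum (relative abundances).

    Zero entries stay zero; an all-zero sample row is an error because it has
    no defined composition.
    """
    sums = table.values.sum(axis=1)
    zero = np.nonzero(sums == 0)[0]
    if zero.size:
        raise FormatError(f"sample {table.sample_ids[zero[0]]!r} has zero total abundance")
    return FeatureTable(
        list(table.sample_ids), list(table.feature_ids), table.values / sums[:, None]
    )


def align_features(
    reference: FeatureTable | Sequence[str], other: FeatureTable
) -> FeatureTable:
    """Reindex ``other`` onto the reference feature set.

    Features absent from ``other`` are zero-filled; features private to
    ``other`` are dropped.  Values are *not* renormalized, so a trained
    model sees test abundances on the same scale it was trained on.
    """
    if isinstance(reference, FeatureTable):
        ref_ids = list(reference.feature_ids)
    else:
        ref_ids = [str(f) for f in reference]
    index = {f: j for j, f in enumerate(other.feature_ids)}
    out = np.zeros((other.n_samples, len(ref_ids)))
    for j, f in enumerate(ref_ids):
        k = index.get(f)
        if k is not None:
            out[:, j] = other.values[:, k]
    return FeatureTable(list(other.sample_ids), ref_ids, out)


def abundance_ubiquity_summary(
    table: FeatureTable,
    feature_ids: Iterable[str] | None = None,
    directions: dict[str, str] | None = None,
) -> list[MarkerSummary]:
    """Mean relative abundance (zeros included) and ubiquity per feature.

    Ubiquity is the fraction of samples in which the feature is detected
    (abundance strictly positive).
    """
    if feature_ids is None:
        feature_ids = list(table.feature_ids)
    else:
        feature_ids = [str(f) for f in feature_ids]
    index = {f: j for j, f in enumerate(table.feature_ids)}
    directions = directions or {}
    out = []
    for f in feature_ids:
        if f not in index:
            raise ConsistencyError(f"unknown feature id: {f!r}")
        col = table.values[:, index[f]]
        out.append(
            MarkerSummary(
                feature_id=f,
                mean_relative_abundance=float(col.mean()),
                ubiquity=float((col > 0).mean()),
                direction=directions.get(f, "none"),
            )
        )
    return out


def subsample_balance(
    metadata: pd.DataFrame, threshold_age: float = 40.0, seed: int = 0
) -> list[str]:
    """Balance young (< threshold) and old (>= threshold) strata by subsampling.

    Returns all samples of the minority stratum plus a seed-deterministic
    uniform subset of the majority stratum of the same size.  Samples at
    exactly the threshold age count as old.
    """
    if "age" not in metadata.columns or "sample_id" not in metadata.columns:
        raise SchemaError("metadata must have 'sample_id' and 'age' columns")
    young = metadata.loc[metadata["age"] < threshold_age, "sample_id"].tolist()
    old = metadata.loc[metadata["age"] >= threshold_age, "sample_id"].tolist()
    if not young or not old:
        raise ConsistencyError("both age strata must be non-empty for balancing")
    rng = np.random.default_rng(seed)
    if len(young) > len(old):
        minority, majority = old, young
    else:
        minority, majority = young, old
    keep = rng.choice(len(majority), size=len(minority), replace=False)
    chosen = [majority[i] for i in sorted(keep)]
    # preserve the metadata row order in the returned subset
    selected = set(minority) | set(chosen)
    return [s for s in metadata["sample_id"] if s in selected]
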