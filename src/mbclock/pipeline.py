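"""End-to-end pipeline: simulate/ingest -> filter -> normalize -> train ->
relative age -> transfer, driven by one YAML config with a global seed.

Every stage writes its artifacts to the output directory and registers them
in a JSON manifest together with parameters, the stage seed, and SHA-256
checksums; rerunning the same config reproduces identical checksums.  Stage
seeds are derived as ``global_seed + stage_index`` so streams are
reproducible but decorrelated.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ConfigurationError, MbclockError
from .filtering import apply_inclusion_criteria, filter_feature_table
from .regressor import (
    ModelConfig,
    TrainedAgeModel,
    predict_microbiota_age,
    tune_and_train,
)
from .relative import compare_groups_wilcoxon, fit_age_spline, relative_microbiota_age
from .synthetic import AgeDistribution, CohortConfig, generate_accelerated_group, generate_cohort
from .tables import (
    FeatureTable,
    read_metadata,
    read_table,
    to_relative_abundance,
    write_metadata,
    write_table,
)
from .transfer import permutation_null_mae, stratified_cross_train

__all__ = ["RunConfig", "run_pipeline", "load_run_config", "save_model", "load_model"]

logger = logging.getLogger("mbclock")

_STAGES = ("simulate", "filter", "normalize", "train", "relative_age", "transfer")

MODEL_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------


def save_model(model: TrainedAgeModel, directory: str | Path) -> None:
    """Persist a trained model as a versioned archive directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "mbclock_version": __version__,
        "feature_ids": model.feature_ids,
        "hyperparameters": model.hyperparameters,
        "importances": model.importances.tolist(),
        "cv_mae": model.cv_mae,
        "cv_predictions": model.cv_predictions.tolist(),
        "training_sample_ids": model.training_sample_ids,
        "training_age_range": list(model.training_age_range),
    }
    (directory / "model.json").write_text(json.dumps(meta, indent=2))
    with open(directory / "forest.pkl", "wb") as fh:
        pickle.dump(model.forest, fh, protocol=4)


def load_model(directory: str | Path) -> TrainedAgeModel:
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    if meta.get("format_version") != MODEL_FORMAT_VERSION:
        raise ConfigurationError(
            f"unsupported model archive version: {meta.get('format_version')!r}"
        )
    with open(directory / "forest.pkl", "rb") as fh:
        forest = pickle.load(fh)
    return TrainedAgeModel(
        forest=forest,
        feature_ids=list(meta["feature_ids"]),
        hyperparameters=dict(meta["hyperparameters"]),
        importances=np.asarray(meta["importances"], dtype=float),
        cv_mae=float(meta["cv_mae"]),
        cv_predictions=np.asarray(meta["cv_predictions"], dtype=float),
        training_sample_ids=list(meta["training_sample_ids"]),
        training_age_range=tuple(meta["training_age_range"]),
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Either ``simulate`` (a synthetic-cohort section) or ``input`` (paths to
    an existing table and metadata TSV) must be provided.
    """

    out_dir: Path
    seed: int = 0
    simulate: dict | None = None
    input: dict | None = None
    apply_filter: bool = True
    model: ModelConfig = field(default_factory=ModelConfig)
    spline_smoothing: float | None = None
    group_column: str | None = None
    stratify_by: str | None = None
    n_perm: int = 1000
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.input is None):
            raise ConfigurationError(
                "exactly one of 'simulate' and 'input' must be configured"
            )
        if self.input is not None:
            for key in ("table", "metadata"):
                if key not in self.input:
                    raise ConfigurationError(f"input section lacks {key!r} path")
                path = Path(self.input[key])
                if not path.exists():
                    raise ConfigurationError(f"input file does not exist: {path}")


def _cohort_config_from_dict(section: dict, seed: int) -> CohortConfig:
    section = dict(section)
    section.pop("kind", None)
    section.pop("n_accel", None)
    section.pop("age_offset", None)
    age = section.pop("age_distribution", None)
    kwargs: dict[str, Any] = {"seed": seed}
    if age is not None:
        kwargs["age_distribution"] = AgeDistribution(**age)
    valid = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(section) - valid
    if unknown:
        raise ConfigurationError(f"unknown simulate option(s): {sorted(unknown)}")
    kwargs.update(section)
    kwargs["seed"] = seed
    return CohortConfig(**kwargs)


def load_run_config(path: str | Path, out_dir: str | Path | None = None,
                    seed: int | None = None) -> RunConfig:
    """Parse a YAML run config; CLI-supplied out_dir/seed override the file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("run config must be a YAML mapping")
    model_section = raw.get("model", {})
    model = ModelConfig(
        n_trees=model_section.get("n_trees", 500),
        mtry_fractions=tuple(model_section.get("mtry_fractions", (0.1, 0.25, 0.33, 0.5))),
        min_node_sizes=tuple(model_section.get("min_node_sizes", (1, 5, 10))),
        cv_folds=model_section.get("cv_folds", 5),
        seed=0,  # overwritten per stage
    )
    return RunConfig(
        out_dir=Path(out_dir if out_dir is not None else raw.get("out_dir", "mbclock_run")),
        seed=int(seed if seed is not None else raw.get("seed", 0)),
        simulate=raw.get("simulate"),
        input=raw.get("input"),
        apply_filter=bool(raw.get("apply_filter", True)),
        model=model,
        spline_smoothing=raw.get("spline_smoothing"),
        group_column=raw.get("group_column"),
        stratify_by=raw.get("stratify_by"),
        n_perm=int(raw.get("n_perm", 1000)),
        log_level=str(raw.get("log_level", "INFO")),
    )


# ---------------------------------------------------------------------------
# execution
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path, config_summary: dict):
        self.out_dir = out_dir
        self.doc = {"mbclock_version": __version__, "config": config_summary, "stages": []}

    def add(self, stage: str, seed: int, params: dict, outputs: list[Path]) -> None:
        self.doc["stages"].append(
            {
                "stage": stage,
                "seed": seed,
                "params": params,
                "outputs": {
                    str(p.relative_to(self.out_dir)): _sha256(p) for p in sorted(outputs)
                },
            }
        )

    def write(self) -> Path:
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(self.doc, indent=2, sort_keys=True))
        return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in fixed order; returns the manifest document.

    Any stage failure aborts the run with the stage name prefixed to the
    error message.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_seed = {name: config.seed + i for i, name in enumerate(_STAGES)}
    manifest = _Manifest(
        out,
        {
            "seed": config.seed,
            "source": "simulate" if config.simulate is not None else "input",
        },
    )

    def fail(stage: str, exc: Exception):
        raise MbclockError(f"stage {stage!r} failed: {exc}") from exc

    # -- simulate / ingest ---------------------------------------------------
    stage = "simulate"
    try:
        if config.simulate is not None:
            sim = dict(config.simulate)
            kind = sim.get("kind", "cohort")
            cohort_cfg = _cohort_config_from_dict(sim, stage_seed[stage])
            if kind == "cohort":
                table, metadata = generate_cohort(cohort_cfg)
            elif kind == "accelerated":
                table, metadata = generate_accelerated_group(
                    cohort_cfg, int(sim.get("n_accel", 0)), float(sim.get("age_offset", 0.0))
                )
            else:
                raise ConfigurationError(f"unknown simulate kind: {kind!r}")
            params = {"kind": kind, **{k: v for k, v in sim.items() if k != "kind"}}
        else:
            table = read_table(config.input["table"], format=config.input.get("format", "tsv"))
            metadata = read_metadata(config.input["metadata"])
            params = {k: str(v) for k, v in config.input.items()}
        table_path = out / "table.tsv"
        meta_path = out / "metadata.tsv"
        write_table(table, table_path)
        write_metadata(metadata, meta_path)
        manifest.add(stage, stage_seed[stage], params, [table_path, meta_path])
        logger.info("simulate/ingest: %d samples x %d features", table.n_samples, table.n_features)
    except Exception as exc:
        fail(stage, exc)

    # -- filter ---------------------------------------------------------------
    stage = "filter"
    try:
        if config.apply_filter:
            report = apply_inclusion_criteria(metadata)
            table = filter_feature_table(table, report)
            metadata = metadata[metadata["sample_id"].isin(set(report.retained_ids))]
            report_path = out / "filter_report.json"
            report_path.write_text(report.to_json())
        else:
            report_path = out / "filter_report.json"
            report_path.write_text(json.dumps({"skipped": True}))
        filtered_path = out / "filtered_table.tsv"
        write_table(table, filtered_path)
        meta_path = out / "filtered_metadata.tsv"
        write_metadata(metadata, meta_path)
        manifest.add(
            stage,
            stage_seed[stage],
            {"enabled": config.apply_filter},
            [report_path, filtered_path, meta_path],
        )
    except Exception as exc:
        fail(stage, exc)

    # -- normalize ------------------------------------------------------------
    stage = "normalize"
    try:
        table = to_relative_abundance(table)
        norm_path = out / "normalized_table.tsv"
        write_table(table, norm_path)
        manifest.add(stage, stage_seed[stage], {}, [norm_path])
    except Exception as exc:
        fail(stage, exc)

    # -- train ----------------------------------------------------------------
    stage = "train"
    try:
        meta_indexed = metadata.set_index("sample_id")
        ages = meta_indexed.loc[table.sample_ids, "age"].to_numpy(dtype=float)
        model_config = dataclasses.replace(config.model, seed=stage_seed[stage])
        model = tune_and_train(table, ages, model_config)
        model_dir = out / "model"
        save_model(model, model_dir)
        preds = predict_microbiota_age(model, table, ages)
        preds_path = out / "predictions.tsv"
        preds.to_frame().to_csv(preds_path, sep="\t", index=False)
        manifest.add(
            stage,
            stage_seed[stage],
            model.hyperparameters,
            [model_dir / "model.json", model_dir / "forest.pkl", preds_path],
        )
        logger.info("train: CV MAE %.2f years", model.cv_mae)
    except Exception as exc:
        fail(stage, exc)

    # -- relative age ----------------------------------------------------------
    stage = "relative_age"
    try:
        groups = None
        if config.group_column is not None:
            groups = meta_indexed.loc[table.sample_ids, config.group_column].astype(str).tolist()
            reference = [i for i, g in enumerate(groups) if g == "control"]
        else:
            reference = list(range(table.n_samples))
        # spline fit on cross-validated microbiota ages of the reference set
        ref_idx = np.asarray(reference if reference else range(table.n_samples), dtype=int)
        spline = fit_age_spline(
            ages[ref_idx], model.cv_predictions[ref_idx], smoothing=config.spline_smoothing
        )
        micro = predict_microbiota_age(model, table).microbiota_age
        result = relative_microbiota_age(
            spline, ages, micro, sample_ids=table.sample_ids, groups=groups
        )
        rel_path = out / "relative_ages.tsv"
        result.to_frame().to_csv(rel_path, sep="\t", index=False)
        outputs = [rel_path]
        if groups is not None:
            labels = sorted(set(groups))
            if len(labels) == 2:
                a = result.relative_age[[g == labels[0] for g in groups]]
                b = result.relative_age[[g == labels[1] for g in groups]]
                stat, p = compare_groups_wilcoxon(a, b)
                cmp_path = out / "group_comparison.json"
                cmp_path.write_text(
                    json.dumps(
                        {"groups": labels, "statistic": stat, "p_value": p}, indent=2
                    )
                )
                outputs.append(cmp_path)
        manifest.add(
            stage, stage_seed[stage], {"smoothing": config.spline_smoothing}, outputs
        )
    except Exception as exc:
        fail(stage, exc)

    # -- transfer --------------------------------------------------------------
    stage = "transfer"
    try:
        outputs = []
        if config.stratify_by is not None:
            model_config = dataclasses.replace(config.model, seed=stage_seed[stage])
            cross = stratified_cross_train(table, metadata, config.stratify_by, model_config)
            matrix_path = out / "transfer_mae.tsv"
            cross.to_frame().to_csv(matrix_path, sep="\t")
            outputs.append(matrix_path)
            # permutation null for the first train->test stratum pair
            a, b = cross.strata[0], cross.strata[1]
            meta_idx = metadata.set_index("sample_id")
            test_ids = meta_idx.index[meta_idx[config.stratify_by].astype(str) == b].tolist()
            test_tab = table.select_samples(test_ids)
            test_ages = meta_idx.loc[test_ids, "age"].to_numpy(dtype=float)
            null = permutation_null_mae(
                cross.models[a],
                test_tab,
                test_ages,
                n_perm=config.n_perm,
                mode="permute_test",
                seed=stage_seed[stage],
            )
            perm_path = out / "permutation.json"
            perm_path.write_text(
                json.dumps({"train": a, "test": b, **null.summary()}, indent=2)
            )
            outputs.append(perm_path)
        else:
            skip_path = out / "transfer_skipped.json"
            skip_path.write_text(json.dumps({"skipped": True}))
            outputs.append(skip_path)
        manifest.add(
            stage,
            stage_seed[stage],
            {"stratify_by": config.stratify_by, "n_perm": config.n_perm},
            outputs,
        )
    except Exception as exc:
        fail(stage, exc)

    manifest.write()
    return manifest.doc
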