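# mbclock

Microbiota-age prediction for 16S amplicon studies: train a tuned
random-forest regressor of host chronological age on ASV relative-abundance
tables, measure its accuracy by mean absolute error (MAE), derive per-sample
**relative microbiota age** against a smoothing-spline reference trend, and
test whether a model trained in one stratum (sex, cohort, body subsite)
generalizes to another using permutation-null significance.

The package is aimed at microbiome researchers who want a tested, scriptable
version of the "microbiome clock" analysis: feature-table and metadata
handling, healthy-adult inclusion filtering, model tuning and evaluation,
marker characterization, and a synthetic-cohort generator that reproduces
the statistical structure such analyses rely on (age-graded markers,
abundance/ubiquity asymmetry between young- and old-enriched taxa,
cohort-private markers, skewed age distributions), so every stage can be
exercised without access to the original cohort data.

## The model

Let `x_i` be the vector of ASV relative abundances of sample `i` (rows
closed to `Σ_f x_if = 1`) and `a_i` its chronological age in years. A random
forest `ĝ` is fit by regressing `a` on `x`, with the mtry fraction and
minimum node size selected by k-fold cross-validated MAE:

    MAE = (1/n) Σ_i |ĝ(x_i) − a_i|

`ĝ(x_i)` is sample `i`'s **microbiota age**. A cubic smoothing spline `f`
(penalty chosen by generalized cross-validation) is fit through the healthy
reference's out-of-fold microbiota ages as a function of chronological age,
and the relative microbiota age of any sample is

    Δ_i = ĝ(x_i) − f(a_i)

Positive `Δ` means an older-looking microbiome. Groups of `Δ` values are
compared with the two-sided Wilcoxon rank-sum test (exact for small tie-free
samples). Whether an observed cross-cohort MAE beats chance is judged
against the MAE distribution under random permutations of the age labels,
with the add-one empirical p-value `p = (1 + #{MAE_null ≤ MAE_obs})/(B+1)`.

## Worked example

```python
import dataclasses
import numpy as np

from mbclock import (
    CohortConfig, ModelConfig, generate_accelerated_group, tune_and_train,
    fit_age_spline, predict_microbiota_age, relative_microbiota_age,
    compare_groups_wilcoxon,
)

# a cohort of 200 healthy adults plus 50 subjects whose microbiome
# looks ten years older than their chronological age
cohort = CohortConfig(n_samples=200, seed=7)
table, metadata = generate_accelerated_group(cohort, n_accel=50, age_offset=10.0)

is_control = (metadata["group"] == "control").to_numpy()
control_ids = metadata.loc[is_control, "sample_id"].tolist()
ages = metadata.set_index("sample_id")["age"]

config = ModelConfig(n_trees=100, mtry_fractions=(0.33,), min_node_sizes=(5,),
                     cv_folds=5, seed=7)
model = tune_and_train(table.select_samples(control_ids),
                       ages.loc[control_ids].to_numpy(), config)
baseline = np.mean(np.abs(ages.loc[control_ids] - ages.loc[control_ids].mean()))
print(f"CV MAE {model.cv_mae:.1f} years vs baseline {baseline:.1f} years")

spline = fit_age_spline(ages.loc[control_ids].to_numpy(), model.cv_predictions)
micro = predict_microbiota_age(model, table).microbiota_age
rel = relative_microbiota_age(spline, metadata["age"].to_numpy(), micro,
                              table.sample_ids)
accel = rel.relative_age[~is_control]
ref = model.cv_predictions - spline(ages.loc[control_ids].to_numpy())
stat, p = compare_groups_wilcoxon(accel, ref)
print(f"median relative microbiota age: accelerated {np.median(accel):+.1f} y, "
      f"reference {np.median(ref):+.1f} y (Wilcoxon p = {p:.2g})")
```

Output:

```
CV MAE 6.3 years vs baseline 18.9 years
median relative microbiota age: accelerated +6.2 y, reference -0.1 y (Wilcoxon p = 9.2e-15)
```

The forest predicts age to within about 6 years on held-out folds — three
times better than always guessing the cohort mean (the baseline of ~19
years). The 50 accelerated subjects sit a median 6 years above the healthy
reference trend, while the reference itself is centred on zero, and the
rank-sum test flags the difference decisively.

## Command line

Every stage is also exposed as a subcommand of `mbclock`:

```sh
mbclock simulate --config cohort.yaml --seed 1 --out sim/
mbclock filter --metadata sim/metadata.tsv --table sim/table.tsv --out filtered/
mbclock train --table filtered/filtered_table.tsv --metadata filtered/filtered_metadata.tsv --seed 1 --out fit/
mbclock predict --model fit/model --table other_cohort.tsv --out preds.tsv
mbclock relative-age --model fit/model --table sim/table.tsv --metadata sim/metadata.tsv --groups group --out rel/
mbclock transfer --table sim/table.tsv --metadata sim/metadata.tsv --stratify-by sex --out mae_matrix.tsv
mbclock run --config run.yaml --out results/   # full pipeline + manifest
```

`mbclock run` executes simulate/ingest → filter → normalize → train →
relative-age → transfer and records every artifact with SHA-256 checksums in
`manifest.json`; a rerun with the same config and seed reproduces identical
checksums.

Tables are read and written as TSV (features × samples, QIIME-style) and as
dense BIOM 1.0 JSON.

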