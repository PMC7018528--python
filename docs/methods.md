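# Methods

This note documents the statistical machinery behind `mbclock`: the model,
the synthetic-cohort generator, the numerical conventions, and the design
choices made where more than one defensible option existed.

## Age regression

Host chronological age is regressed on ASV relative abundances with a
random forest. The tuning grid covers the two hyperparameters that matter
most for forests on wide compositional tables:

| parameter | default | meaning |
|---|---|---|
| `n_trees` | 500 | ensemble size; variance of predictions decays with it |
| `mtry_fractions` | 0.1, 0.25, 0.33, 0.5 | candidate fractions of features tried per split |
| `min_node_sizes` | 1, 5, 10 | candidate minimum samples per leaf |
| `cv_folds` | 5 | folds for tuning and for reported CV MAE |

The winner is the combination with the lowest cross-validated MAE; ties go
to the smaller mtry fraction, then the smaller node size, so tuning is
deterministic. Fold assignment is a seeded shuffle without age
stratification. The tuned model is refit on all samples; its out-of-fold
predictions (from the winning configuration) are retained, because the
reference spline (below) must be fit to predictions that are not
resubstitution-optimistic. Feature importances are the forest's internal
impurity (variance-reduction) scores; the importance ranking breaks exact
ties lexicographically by feature id so it is reproducible.

Forest predictions are averages of training responses, so every microbiota
age lies inside the training age range; this is asserted as a property test
rather than assumed.

**Top-k feature curves.** To ask how many ASVs a good model needs, the
forest is retrained on the k top-ranked features for increasing k. The
ranking is recomputed inside each CV training fold, so the held-out fold
never influences feature selection; with k equal to the full feature count
the procedure reproduces the full model's CV MAE exactly under the same
seed, which pins down the implementation. Hyperparameters are tuned once on
the full table and reused across k (per-k retuning would multiply cost for
little gain and blur the curve's interpretation).

**Cross-stratum transfer.** A model trained inside one stratum is applied
to the others after feature alignment: test features absent from training
are zero-filled and test-private features dropped, with no renormalization,
so the model sees abundances on its training scale. The transfer matrix's
diagonal reports CV MAE, not resubstitution, so within- and cross-stratum
entries are comparable.

**Permutation null.** Significance of an observed MAE is assessed against
MAEs recomputed under shuffled age labels: `permute_test` shuffles test
ages against fixed predictions (cheap, default), `permute_train` retrains
per shuffle (expensive, exposed but never silently merged with the other
mode). The empirical p-value uses the add-one estimator and counts ties
against significance, so p is never 0 and never anti-conservative at the
floor `1/(B+1)`.

## Relative microbiota age

A cubic smoothing spline maps chronological age to expected microbiota age
in the healthy reference; the roughness penalty is chosen by generalized
cross-validation unless set explicitly. Observations sharing a chronological
age are merged into weighted means first, which leaves the penalized
least-squares problem unchanged. The spline is fit in the orientation
"microbiota age as a function of chronological age" — the only orientation
under which the relative-age definition (observed minus expected at the
same chronological age) is meaningful. Evaluation outside the fitting
domain clamps to the boundary value with a warning, because smoothing
splines extrapolate linearly and unreliably. At least 5 distinct
chronological ages are required for the cubic fit.

Group differences in relative age use the two-sided Wilcoxon rank-sum test:
exact null distribution when `n_a * n_b <= 400` and the pooled values are
tie-free, otherwise the normal approximation with continuity correction and
mid-ranks. The exact branch is verified in the test suite against full
enumeration of rank assignments for all group sizes up to 6.

## Healthy-adult filtering

Samples are retained when age ∈ [18, 90] years, BMI ∈ [18.5, 30] kg/m²
(both intervals read as closed), all health/status flags are false (IBD,
diabetes, antibiotics within a month, pregnant, hospitalized, disabled,
critically ill), and no criterion value is missing. Each removal is
attributed to the first criterion failed, in a fixed order, and samples
whose only defect is a missing value are counted under `missing_values`;
this makes the attrition counters deterministic and exactly conserving
(retained + removed = input). Missing values exclude conservatively because
the metadata are self-reported. Age exactly 40 counts as "old" in the
young/old balancing utility (the stratum boundary itself had to be assigned
somewhere; the choice is fixed and documented).

## The synthetic cohort generator

The generator produces the data structure the analysis assumes, not
sequences or phylogeny. Per ASV, a log-normal baseline abundance is drawn;
marker ASVs add a linear age term on the log scale (slope `±effect_size`
per year, centred at age 54, the midpoint of the adult range); per-sample,
per-feature Gaussian log-noise is added; abundances below a detection floor
are zeroed; rows are closed to unit sum last.

Defaults define the study conditions: 500 samples, 200 ASVs, 25
young-enriched plus 25 old-enriched markers, effect size 0.05 per year
(a ~36-fold change across the 72-year adult span), log-noise SD 1.0,
detection floor e⁻⁵ on the raw scale, ages uniform on [18, 90].

Three structural choices matter:

* **Abundance/ubiquity asymmetry.** Young markers get a high baseline
  (log-mean −2, like the background median) and old markers a very low one
  (log-mean −6), so the detection floor makes old markers sparse while
  young markers stay near-ubiquitous. The *presence* of an old-enriched
  ASV is thereby itself informative about age, mirroring how the two marker
  classes behave in real gut and oral communities.
* **Heavy-tailed background.** Background baselines have log-SD 2, so a few
  dominant taxa carry most of each sample's mass, as in real communities.
  This is also a deliberate safeguard: compositional closure transmits any
  age trend in the total marker mass onto every other feature's relative
  abundance. With markers kept to a small share of total mass and the
  denominator dominated by idiosyncratic heavy-tailed background variation,
  that closure-induced signal is far below the denominator noise, so
  cohorts that share *no* marker ASVs genuinely carry no transferable age
  signal — without this, cross-cohort "transfer" would succeed through the
  closure artifact alone.
* **Cohort-private markers.** In multi-cohort generation, a configurable
  fraction of each cohort's markers keeps ids shared by all cohorts (and
  carries signal everywhere); the rest get cohort-private ids and are
  exactly zero elsewhere. Background ASVs are shared. This reproduces the
  situation where a top-ranking marker in one population is undetectable in
  another.

Optional features: right-skewed ages (18 + Gamma(shape, scale 5), truncated
at 90 by resampling — a young-heavy histogram typical of crowdsourced
cohorts); a female-restricted marker subset (`sex_effect`), which degrades
male↔female transfer qualitatively; a configurable fraction of samples
violating each exclusion criterion, to exercise the filter; and an
"accelerated" group whose marker profiles are generated at `age + offset`
while the recorded age is unchanged — controls are drawn identically to a
plain cohort with the same seed, and accelerated samples use an independent
stream, so adding the group never perturbs the controls.

What the generator does **not** emulate: phylogenetic correlation between
ASVs, longitudinal structure, batch/primer effects, taxon-taxon
interactions, non-monotone age trajectories, and realistic zero-inflation
beyond the detection floor. Tests passing on these cohorts therefore
demonstrate correctness of the machinery and sane statistical behaviour
under the assumed structure — not performance on any real cohort.

## Numerical conventions

* Compositional closure to row sum 1 ± 1e-9; zeros preserved; all-zero
  rows are an error in normalization (no defined composition).
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; forests use a fixed `random_state`; reruns
  are bitwise reproducible, which the pipeline verifies by SHA-256
  checksums of every artifact.
* Pipeline stage seeds are `global_seed + stage_index`.
* Feature alignment never renormalizes; the only closure happens in
  `to_relative_abundance`.
* Problem sizes in the test suite and acceptance script (forests of
  60–100 trees, cohorts of 120–500 samples, 200 permutations) are scaled-
  down versions of the library defaults (500 trees, 1000 permutations),
  chosen so the full suite runs in a few minutes on one CPU while leaving
  every statistical conclusion unchanged.

## Known limitations

* The empirical p-value floor is `1/(n_perm + 1)`; with the default 1000
  permutations, no p below ~0.001 can be reported.
* GCV smoothing can undersmooth when microbiota ages contain strong
  age-dependent heteroscedasticity; the penalty is overridable.
* The exact Wilcoxon branch requires tie-free data; with ties the normal
  approximation is used even for small samples (mid-ranks, continuity
  correction).
* Dense BIOM JSON only; sparse/HDF5 BIOM is out of scope.
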