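# Methods

## Data model

A cohort is a rats × measurements matrix with a %TBSA group label per rat
(0 = sham, 20, 40; any ordered dose levels are supported).  A measurement
series is an analyte in one compartment — HA and PV (liver inflows), SHVC
(outflow), or FLUX (derived trans-liver flux).  Units are heterogeneous
(mg/dL, µM, %, mmHg, mL/min) and are carried as opaque metadata; nothing in
the pipeline depends on them because profiles are normalized per variable.
Missing cells are an explicit not-a-value sentinel (NaN / empty CSV cell),
never zero.

The packaged summary panel (`table1_summary.csv`) transcribes the published
per-group medians and IQRs for 165 series (55 analytes × 3 vessels) together
with the cluster label the original analysis assigned to each series.  The
transcription preserves print order (`source_row`) and the printed variable
wording (`printed_label`), including its irregularities: one HA row is
printed with an ambiguous aminotransferase label and is keyed as AST (its
values duplicate the HA ALT row), so that every analyte appears exactly once
per vessel and discrepancies stay auditable.

## Preprocessing

* **Outlier fence.** Within each (variable, group), cells outside
  median ± 2·IQR are masked to missing.  Median and IQR are computed on the
  pre-masking values, so the fence cannot drift as cells are removed.
  Quartiles use linear interpolation on the sorted sample (numpy's default,
  "type 7"); the convention is configurable because the original analysis
  environment does not document one.  A zero IQR collapses the fence onto
  the median, so any deviating value masks; this edge is logged.
* **Rat exclusion.** Rats whose missing fraction over the *measured vessel
  concentration* columns (derived fluxes excluded) strictly exceeds 0.30 are
  dropped.  At exactly 30% a rat is kept.
* **Imputation.** Remaining holes are filled with the median of the
  observed values of that (variable, group); a fully missing
  (variable, group) is an error naming the offender.  Imputation is
  idempotent and never alters observed cells.
* **Fluxes** are derived only after imputation, so no flux is built from a
  missing concentration.  Outflow is assumed to equal the summed inflow
  (`Q_out = Q_PV + Q_HA`), giving
  `flux = (Q_out·C_SHVC − Q_PV·C_PV − Q_HA·C_HA) / W_liver`,
  positive for net hepatic release, in concentration·mL·min⁻¹·g⁻¹.
* **Profiles.** The per-group statistic (mean by default; median mode exists
  for summary-driven runs) is mapped affinely so its minimum is −1 and its
  maximum +1; a constant profile maps to (0, 0, 0).  Profiles are therefore
  invariant to positive affine rescaling of the raw units.  Note the
  normalization has no "small effect" regime: a variable whose group means
  differ only by noise still spans the full [−1, 1] range.

## Synthetic cohorts

Only per-group medians and IQRs were ever published, so synthetic cohorts
draw each cell from Normal(median, IQR/1.349) — the normal-theory IQR↔sd
conversion — truncated at zero by rejection for non-negative quantities
(concentrations and flows; fluxes may be negative).  A log-normal family
matched to the same median and spread is available for heavier tails, off by
default.  Group sizes default to the study design (12/12/13).  Liver weight
is a generator parameter, Normal(10 g, 1 g) by default — a plausible value
for ~300 g rats; the source prints none.  An optional shared group-level
latent shift per variable emulates metabolite correlation and is off by
default.

Injected artefacts exercise the preprocessing filters: missingness is
Bernoulli per cell (default 5%); outliers (default 2%) are placed just
beyond the 2·IQR fence plus `outlier_scale` (default 3) further IQRs, on a
random side, the negative side being avoided when it would violate
non-negativity.  Because the same seed drives the same uniform draws, the
set of rats exceeding the 30% missingness bar is pointwise monotone in the
missingness rate.

What the generator does **not** emulate: inter-metabolite correlation (off
by default), distributional skew (unless the log-normal family is chosen),
measurement batch effects, and longitudinal time courses (the design is a
single day-4 snapshot).  Tests that pass on these cohorts validate the
pipeline's mechanics and its behaviour under the stated noise model — not
the biology of any particular real cohort.

For selection-recovery experiments, `plant_signal` flattens every variable's
group medians to their mean except a chosen signal set, so only the planted
variables carry a dose effect while the noise floor stays summary-calibrated.
The packaged experiment plants a VLDL-like monotone decrease (13 → 6 → 5)
and an acetoacetate-like step-down (126 → 126 → 31) with IQRs set to 10% of
each group median's magnitude — the printed relative precision of the
headline indicator itself (its IQRs are 4–17% of its medians).  The printed
spread of the ketone-body rows is not used for the planted pair because it
is dominated by a heavy upper tail (the source analysis itself flags ketone
bodies as its noisiest measurements), which would make the "planted strong
signal" premise false by construction.

## Clustering and k selection

K-means uses plain Lloyd iteration on the normalized 3-vectors with
Euclidean distance; each restart is initialized from k distinct randomly
chosen profiles (no ++-style seeding, matching the era's default), and an
emptied cluster is re-seeded from the farthest point.  The best of
`replicates` (default 10) restarts by within-cluster error is kept; the
error is the k-means objective (sum of squared distances) by default, with
an unsquared option since the source analysis did not state which it
plotted.  Silhouettes are standard Euclidean silhouettes over all points;
singleton clusters score 0 by convention.  On the packaged panel the k = 4
optimum is unique: with ample restarts (≈500), runs from unrelated seeds
land on identical centroids.

The number of clusters is chosen by a tandem rule that formalizes the usual
visual elbow-plus-silhouette inspection: the smallest k whose mean
silhouette is a local maximum of the scan (boundary peaks count) and beyond
which no scanned k offers a relative silhouette gain of
`silhouette_gain_threshold` (default 0.05) or more.  The 5% default encodes
the judgement that a ~2% gain is marginal while a ≳8% gain is not.

## Independent patterns

Each cluster is summarized by its per-level member median; the columns form
a 3 × k centroid matrix, decomposed by SVD *without centering* (the object
of interest is the patterns themselves, not their deviations from a mean
pattern).  The pattern count keeps singular values that are (i) above an
absolute floor `tol = 1e-2`, (ii) distinct — values within `tol` of each
other merge, top-down — and (iii) not marginal: counting stops at the
smallest n whose residual squared-singular-value share falls below
`residual_energy_tol` (default 0.02).  The residual-energy criterion is the
operative definition of "marginally non-zero singular values are artifacts
of measurement error and clustering"; a bare threshold on the singular
values themselves cannot express it (a pattern carrying 1.5% of the energy
of a 3 × 4 matrix still has a singular value of ~0.4).  "Total variability"
means the sum of squared singular values; a linear-sum mode exists for
sensitivity checks.  On the packaged panel with the published labels the
singular values are (2.225, 2.105, 0.403): two independent patterns carrying
98.3% of the energy.

The variable budget of the downstream regression defaults to this pattern
count.

### The printed-medians proxy

Profiles built from the packaged panel use printed group *medians* where the
original analysis clustered group *means* of per-rat data.  The proxy
reproduces the pattern-level results (two independent patterns, the
cross-vessel membership set) but not the fine cluster geometry: printed
medians are coarsely quantized, so dozens of profiles coincide exactly
(constant-median rows all map to (0, 0, 0)), and mean silhouette keeps
rising well past four clusters as k-means isolates those coincident clumps.
On this proxy the tandem rule settles at k = 7, and the silhouette gain from
four to six clusters is ≈7–9% rather than the ~2% observed on the original
per-rat means.  The acceptance suite computes and reports these numbers as
they are; they measure the proxy, not a defect of the selection rule (which
recovers k = 4 on archetype cohorts in 10/10 seeds at moderate noise).

## Severity index

* **Metric.** RAE = 100·Σ|ŷ − y| / Σ|ȳ − y| with the mean of the training
  targets as baseline ȳ; "average relative accuracy" is 100 − RAE (negative
  when a model is worse than the baseline).  The definition is validated by
  recomputing the published per-rat index errors exactly (8.49% and 2.54%).
* **Cross-validation.** Five repetitions of 10-fold CV; each repetition
  draws a fresh shuffled partition and a fresh model seed.  A repetition's
  RAE pools held-out absolute errors over its folds, each fold's baseline
  being its own training mean; the report is the mean ± sd of accuracy
  across repetitions (repetition-level averaging).  Folds are unstratified
  by default, as is usual for regression.
* **Regressors.** OLS; linear-kernel SVR (C = 1, ε = 1e-3, standardized
  inputs); a one-hidden-layer perceptron with ⌈(p+1)/2⌉ logistic units
  trained by plain-momentum SGD (rate 0.3, momentum 0.2, 500 epochs,
  standardized inputs, identity output); a normalized-Gaussian RBF network
  (k-means centers, default 2; width = nearest-center distance; ridge
  readout); and a variance-reduction model tree with ridge-stabilized linear
  leaf models (min 4 cases per leaf).  The model tree covers the
  piecewise-linear family generically; it is not a re-implementation of any
  particular historical tool.  All hyperparameters are fixed defaults — no
  tuning layer exists.
* **Wrapper selection.** A genetic algorithm over variable bitmasks
  (population 20, generations 20, one-point crossover at rate 0.6, bit-flip
  mutation at rate 1/p, elitism 1, tournament size 2) with cross-validated
  accuracy as fitness, followed by a best-first forward search with
  backtracking (stale limit 5) restricted to the GA-selected pool, returning
  exactly `budget` variables; the final set is re-scored with the full
  5 × 10-fold protocol.  Two design points matter when candidates far
  outnumber rats (165 vs 21): the initial population is sparse (per-bit
  density min(0.5, max(5, 2·budget)/p)), because the fitness of
  half-the-panel subsets is uninformative noise; and the best-first pool is
  the union of the final generation's genes plus the best mask, which is
  robust to a single mask having dropped a good variable.  GA fitness uses
  one CV repetition for tractability; everything is driven by one seed and
  fully reproducible.
* **Recovery experiment scale.** The packaged planted-pair experiment runs
  ten 21-rat cohorts (7/7/7, the study's retained design) over the full
  165-variable panel, scoring search fitness with the OLS model: the planted
  pair is linearly identifiable, and the experiment probes the search layer,
  not the regressor family.  The perceptron's full 5 × 10-fold accuracy is
  then evaluated on the recovered pair.  Recovery is not guaranteed per
  seed — with 21 rats and 163 noise variables an impostor subset can
  legitimately out-score the truth under cross-validation — which is why the
  criterion is a success fraction over seeds.

## Pipeline

One master seed drives every stage seed through SHA-256 hashing of the
stage name, so stages cannot covertly share randomness and a manifest fully
determines re-execution; manifests are canonicalized (sorted keys, floats
rounded to 12 significant decimals, no timestamps) and byte-identical across
reruns.  In median mode (summary table only) the per-rat selection stages
are skipped; in simulate and cohort modes the full chain runs and the
manifest records the preprocessing audit trail, the k scan, the pattern
analysis, per-model selections and the final index.

## Known limitations

* The printed-medians proxy limits fidelity at the cluster-geometry level
  (see above); per-rat results in the original study are not reproducible
  without the undeposited data, and the cross-validated accuracies reported
  there are replaced by the planted-signal recovery properties.
* The Decision Table and rule-based piecewise models of the original
  comparison are represented by the generic model tree only.
* The generator's noise model is symmetric by default; analytes with
  strongly skewed distributions (ketone bodies) are under-served unless the
  log-normal family is enabled.
* Three dose levels cannot localize a critical injury threshold; the
  pattern analysis deliberately makes no such claim.
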