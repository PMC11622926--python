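# Methods

## Model and procedure

The pipeline addresses binary classification of clinical tabular records
with wrapper feature selection. It has four stages, run in a fixed order:

1. **Preprocessing.** Missing cells are imputed by k-nearest neighbours
   (default k = 5): neighbour candidates are the fully observed rows,
   distances are Euclidean over the columns observed in the query row
   (pairwise-complete), ties break toward lower row index, and each missing
   cell takes the mean of its column over the k neighbours. In discrete
   (integer-coded) columns the mean is rounded to the nearest code so the
   column type is preserved; continuous columns keep the exact mean.
   Continuous columns are then min-max scaled to [0, 1]; two-level discrete
   columns are presence-encoded to {0, 1}; any feature pair with absolute
   Pearson correlation above 0.95 (or exact duplication) drops the later
   column. Degenerate constant columns scale to all zeros under both min-max
   and z-score; z-scores use the population (not sample) standard deviation.

2. **KeRF ranking.** The kernel-random-forest estimator is the average over
   trees of the within-cell mean response, with leaf membership stored
   against the original training rows so the kernel form is exact. Trees
   grow breadth-first on bootstrap resamples; at each node ceil(sqrt(d))
   candidate features are drawn, each with one uniform random threshold
   inside the node's value range, and the lowest weighted Gini impurity
   wins; growth stops at max_depth (default 10) or a per-tree leaf budget of
   ceil(sqrt(n)). A query landing in a cell with no training rows
   contributes zero for that tree (a skip-and-renormalize variant is
   available behind `empty_cell="skip"`). Feature importance is split
   frequency — the share of internal nodes splitting on each feature — which
   sums to one whenever any split exists; ranking ties break toward the
   lower feature index. The optional random Fourier map uses
   omega ~ N(0, 2*gamma) and phase ~ U[0, 2*pi), approximating
   exp(-gamma ||x-y||^2) (gamma default 1.0); ranking is always computed on
   the original columns so selected indices refer to the input table.

3. **BHO refinement.** Default 30 stars, 100 iterations, over the KeRF-
   retained features (retention defaults to all features, i.e. the
   pre-filter is off unless `keep_features` is set, because it is an open
   design choice whether the mask search should see the full table).
   Fitness is the hold-out accuracy (stratified 80/20, fixed split seed) of
   a 50-tree random forest on the masked columns; fixing the split across
   masks makes fitness a deterministic function of the mask and keeps
   comparisons between masks low-variance. All-zero masks are invalid:
   redrawn at initialization, scored 0 if produced by an update. Ties in
   the black-hole selection prefer fewer features, then lower star index.
   Duplicates of the black hole are replaced (redraw until distinct) before
   the position update within each iteration; an optional Hamming event
   horizon of radius ceil(f_bh * d / sum_i f_i) absorbs near stars (off by
   default, since the absorption rule appears only in narrative form). The
   update step is fixed at 0.7; an alternative "inheritance" mode copies
   each bit from the black hole with probability 1/2. Fitness values are
   cached by mask bits, so the evaluation count is bounded by
   num_stars * (max_iter + 1).

4. **Boosted classification.** XGBoost with logistic loss under a fixed
   configuration: learning rate 0.1, max depth 6, L2 penalty 1, L1 penalty
   0.5, up to 100 rounds, logloss early stopping after 10 stale rounds when
   a validation set is supplied. The outer protocol is a stratified 80/20
   split (|test| = round(0.2 n)) with stratified 5-fold cross-validation on
   the training part; per-fold metrics use each fold's validation part for
   early stopping, and the final model is refit on the full training part
   without early stopping (using the test set for stopping would leak).
   Metrics are recomputed from confusion counts; a rate with a zero
   denominator is reported as 0 and flagged `undefined` rather than NaN so
   fold averages stay finite. Cohen's kappa is
   (observed - expected) / (1 - expected) with expected agreement from the
   marginals; when expected = 1 the convention is kappa = 1 for perfect
   agreement, else 0. The positive label is 1 = disease (configurable).

## Synthetic data: what it emulates, and what it does not

`generate_cleveland_like` draws the 13-attribute heart-disease schema —
continuous columns uniform over plausible clinical ranges (age 29-77,
cholesterol 120-420 mg/dL, resting BP 90-200 mmHg, max heart rate 70-210,
ST depression 0-6.2), discrete columns uniform over their code sets — and a
binary diagnosis from a logistic model over a planted informative subset:
P(y=1) = sigmoid(b0 + sum_j beta_j z_j + eps), with z_j the standardized
informative columns, eps ~ N(0, noise_sd), and b0 bisected so the mean
probability hits the requested prevalence (default 0.5). Defaults: n = 350
records, effects {chol +6.0, cp +5.5, oldpeak +5.8, thalach -5.2},
noise_sd 0.25, 2% missing cells. At these defaults the design's Bayes
accuracy — the mean of max(p, 1-p) over the generator's own class
probabilities — is about 0.95 (measured at n = 20000), so a well-tuned
classifier on the informative columns has clear headroom over the ~0.5
majority baseline. The generator emulates schema, ranges and signal
structure only: columns are independent given the label mechanism, there
are no inter-feature correlations, measurement artefacts or cohort effects,
so passing tests demonstrate that the machinery recovers a planted signal,
not that it matches any clinical cohort's distribution.

`generate_sensor_stream` draws fused wearable records (heart rate, PR
interval, temperature, systolic/diastolic pressure, SpO2). The normal
region is exactly the product of the stated intervals; a record is
abnormal (label 1) iff any rule fires strictly: heart rate < 60 or > 100
bpm, PR interval > 0.2 s, temperature > 100.4 F, systolic >= 130 or
diastolic >= 81 mmHg, SpO2 < 95%. Boundary equality labels 0. Systolic
120-129 with diastolic <= 80 counts as elevated but still normal (label 0).
Labels stored by the generator always equal the rule function reapplied to
the values.

`generate_echo_images` writes two class folders of 64x64 grayscale PNGs
(noisy field plus a bright horizontal band whose position and brightness
are class-dependent). These are synthetic stand-ins with a designed,
easily separable signal — a pipeline smoke target, not imaging realism.

## Numerical conventions and degenerate inputs

- Missing marker: NaN internally; empty CSV fields plus a configurable
  sentinel (default "NA") on input; empty field on output. CSV round-trips
  are exact (floats written with full repr precision).
- Constant columns: min-max and z-score return all zeros; correlation
  against a constant column is treated as undefined (never triggers
  redundancy removal) except for exact duplicates, which always drop.
- KeRF prediction at a query equals the literal kernel double sum to 1e-10
  (tested against an independent enumeration); with all cells non-empty the
  prediction lies in [min y, max y].
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); the pipeline derives its stage seeds as
  (seed, seed+1, seed+2, seed+3) for the KeRF fit, the star population, the
  fitness split and the 80/20 split, so one integer reproduces the whole
  manifest. XGBoost and the inner random forests run single-threaded with
  fixed `random_state` for bit-reproducibility.
- Human-readable CLI output rounds to 4 decimal places; JSON artefacts keep
  full precision.

## Problem sizes

Tests and the acceptance script run the method at reduced but meaningful
sizes chosen for quick iteration: the end-to-end check uses n = 1000 rows
with a 15-star x 25-iteration search (the planted signal is strong enough
that convergence is fast); the feature-recovery check uses the stated
n = 500 with 20 stars x 40 iterations over 10 seeds; Monte-Carlo checks of
the transfer rule use 1e5 draws. Defaults in the library itself remain the
full 30 stars x 100 iterations and 100 trees.

## Known limitations

- Binary targets only; multi-class labels are out of scope.
- The BHO fitness is a single fixed hold-out accuracy; no inner
  cross-validation (cheap and deterministic, but a noisy estimate at small
  n — the elitist best-ever mask partially compensates).
- Split-frequency importance is biased toward high-cardinality continuous
  features, as all frequency-based tree importances are.
- The redundancy filter is greedy by column order (the later column drops),
  not a graph-optimal de-duplication.
- No probability calibration or ROC analysis; metrics are threshold-based
  at p > 0.5.
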