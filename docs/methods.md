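# Methods

`virtualsdm` implements a virtual-ecologist experiment: because the true
distribution of a real species is unknowable, it simulates species whose
suitability surface and range are known exactly, pushes them through the very
modelling routine an empirical study would use, and measures how much of the
truth survives. This note records the models, the defaults, and the design
choices that were genuinely open.

## Synthetic environment

Layers are Gaussian random fields: white noise smoothed with a Gaussian
kernel (`smoothness`, in cells; default 5), plus a linear spatial gradient of
random orientation (relative weight 0.3) that gives each layer the
continental-scale trend typical of climate surfaces. Fields are standardised
and mixed through the Cholesky factor of a target correlation matrix, so the
empirical inter-layer correlations approximate the target; a per-layer affine
rescaling afterwards puts layers on climate-like scales without touching
correlations. Generation is bit-reproducible given the seed.

The default correlation template has 27 layers — 15 "base" variables with
uniform pairwise correlation 0.3 and 12 near-duplicates at correlation 0.97
to distinct bases, built from an explicit factor model so the matrix is
positive semi-definite by construction. This reproduces the situation that
makes collinearity screening meaningful: iterative VIF elimination at the
conventional threshold of 10 removes roughly the dozen redundant layers
(exactly 12 of 27 on the default seed). The retained count is a property of
the generator, not something the pipeline asserts.

Two grid resolutions are related by a factor-4 bilinear downscaling (default
100×100 high grid → 25×25 low grid), mirroring a 2.5 vs 10 arc-min pair.
Grids are planar (no geodesy), row-major with row 0 northernmost, and use
cell-centre coordinates; rasters travel as ESRI ASCII grids on disk and as
NaN-masked arrays in memory.

## Virtual species

A species is a bivariate Gaussian response centred at the origin of the
first two PCA axes of (by default) the first four layers — the small set of
"causal" variables — with the axes z-standardised so niche breadth is in
axis-standard-deviation units. Breadth encodes specialisation:

| label                  | σ (both axes) |
|------------------------|---------------|
| generalist             | 0.8           |
| restricted_generalist  | 0.6           |
| relaxed_specialist     | 0.4           |
| specialist             | 0.2           |

Per-cell suitability is the **product** of the two axis responses (one
strongly hostile variable suppresses suitability regardless of the other),
rescaled to maximum 1; the "true" range is the set of cells with suitability
≥ 0.2 (boundary inclusive). Three choices here were open and are ours:

* the max-1 rescaling — without it a fixed 0.2 threshold could empty a
  narrow niche's range, and it makes the threshold comparable across
  specialisation levels;
* isotropic breadth (σ₁ = σ₂) — specialisation is a single level, not
  axis-specific;
* "covering X% of the environmental range" is operationalised as σ = X/100
  on the standardised axes; no separate coverage percentage is computed or
  verified;
* PCA components are oriented so the largest-magnitude loading is positive,
  which makes niches reproducible under layer reordering.

## Occurrence sampling and positional error

Presences are rejection-sampled from the presence region: a uniform random
presence cell is offered and accepted with probability equal to its
suitability, so a pixel with occurrence probability 0.8 yields a record on
80% of offers and sampling frequencies are proportional to suitability.
Absences are drawn from outside the range and accepted with probability
1 − suitability. Accepted records are placed uniformly within their cell.
Offers are capped; exhausting the cap (a pathological species) is an error,
not a silent short count.

Positional error has four levels. Level 0 leaves coordinates untouched.
Level k ∈ {1,2,3} displaces each record in a uniformly random direction by a
distance uniform in (k·w, (k+1)·w], w the cell width — just outside a buffer
of k pixels around the true location. "Outside the buffer" alone is
unbounded; the annulus keeps the error magnitude tied to the level. Points
displaced off the map are re-drawn rather than clipped, avoiding edge
pile-up. Sampling bias, imperfect detection and misidentification are out of
scope: the experiment manipulates sample size and positional accuracy only.

## Modelling

Predictors are screened by iterative VIF elimination (drop the largest VIF,
recompute, stop when all ≤ 10; ties broken toward the earliest layer; a
fixed seeded subsample of ≤ 50,000 cells keeps large grids tractable).
Models never see the two PCA axes the species was built from — they see the
reduced predictor stack, as an empirical study would.

Five presence-background algorithms share one fit/predict contract, with
hyperparameters pinned for reproducibility rather than tuned per species:

* **GLM** — logistic regression with linear + quadratic terms, unpenalised;
* **GAM** — logistic additive model as a cubic regression-spline basis
  (4 knots) per predictor with a ridge penalty (C = 1);
* **GBM** — gradient-boosted trees: 2500 trees, depth 7, learning rate
  0.001 (the conventional boosted-SDM defaults);
* **RF** — random forest, 500 trees, class-probability output;
* **MAXENT** — a maxnet-style penalised logistic regression on linear,
  quadratic and forward/reverse hinge features (5 knots per direction,
  min–max scaled predictors, L1 penalty with regularisation multiplier 1).
  This is the penalised-GLM formulation of maximum-entropy modelling, not
  the Java application.

GLM, GAM, GBM and RF are fitted with a 0.5-prevalence weighting (presences
and background carry equal total weight), so predicted probabilities are not
deflated by the presence:background ratio — important because the agreement
metrics compare predicted surfaces to the true suitability on an absolute
scale. MAXENT keeps the raw contrast; its output is a relative index.

Each configuration cell runs 5-fold cross-validation × 5 background
replicates = 25 fits. Each replicate draws a fresh uniform background sample
(default 1000 points; the background size is a convention, not a measured
quantity). Presences and background are split into folds separately, so
every held-out fold contains both classes. With n = 5 presences the training
folds hold 4 presences; fits require ≥ 2 presences and cross-validation
requires n ≥ k folds.

## Evaluation

* **AUC** — Mann–Whitney rank formulation, ties counted ½.
* **TSS** — sensitivity + specificity − 1, maximised over candidate
  thresholds (the observed scores plus 0 and 1; prediction positive iff
  score ≥ threshold; ties broken toward the lower threshold).
* **Standard** metrics score each run's held-out presences vs background —
  what an empirical study can compute. **Independent** metrics score fresh
  draws of 500 presences and 500 *true* absences from the known range — what
  an empirical study cannot. A "good model" has median AUC ≥ 0.7 or median
  TSS ≥ 0.4.
* **Schoener's D** — surfaces normalised to total mass 1, D = 1 − ½Σ|p₁−p₂|;
  invariant to positive rescaling.
* **OCCC** — for a pair of surfaces this is Lin's concordance,
  2·s₁₂ / (s₁² + s₂² + (m₁−m₂)²), with population (n-denominator) moments;
  the sample-moment variant differs at small n, so the convention matters
  and is fixed here. The signed value is returned (concordance can be
  negative); any clamping is left to reporting.

Agreement is computed against the continuous true suitability, not the
binary range, and additionally between each degraded-occurrence prediction
and the matching precise-occurrence prediction of the same (replicate, fold)
run.

## Experiment and statistics

The full factorial design is 4 species × 5 algorithms × 2 resolutions × 6
sample sizes (5–200) × 4 precision levels × 25 runs = 24,000 model runs. All
per-cell randomness is derived by hashing the master seed with the factor
levels, so any cell is reproducible in isolation, results are independent of
execution order, and occurrence/background draws are shared across
algorithms within a cell (five engines, one dataset). Per-cell failures are
logged and skipped, not fatal; a checkpoint directory makes long runs
resumable. Summaries report per-group medians and inter-quartile ranges.
Whether minimum-sample-size statements should rest on standard or
independent metrics is genuinely ambiguous — the package reports both; the
qualitative checks in the test suite read the independent AUC (the
reliability-oriented answer) and verify the standard good-model rule agrees.

Statistical comparisons: one-sample Wilcoxon of the 25 standard metrics of a
cell against the independent reference (exact null for n ≤ 25 without ties,
else normal approximation with continuity correction; exact zeros dropped —
Wilcoxon's original policy, noted because the Pratt variant changes p);
two-sample Wilcoxon between resolutions (exact for tie-free pooled n ≤ 25);
and an OLS factor analysis of exp(AUC) on the five factors, all categorical
(sample size has discrete design levels), with and without all two-way
interactions, compared by AIC (Gaussian log-likelihood convention; only AIC
differences are meaningful and they are invariant to the additive constant).
The drop-one table lists both full models and the no-interaction model minus
each factor, with the factor's parameter count as its df.

## Problem sizes used in the shipped checks

The test suite exercises a reduced design chosen to finish on a laptop: a
100×100, 27-layer stack; generalist and specialist; GLM and RF; n ∈
{10, 200}; precision levels {0, 3}; 25 runs per cell (400 runs total). On
that design the package reproduces the qualitative pattern the full design
is built to show: agreement with truth rises with sample size everywhere,
the precise-vs-displaced OCCC drop (matched within algorithm × sample-size
cells) is larger for the specialist than the generalist, and a generalist
GLM crosses the good-model bar with ten precise occurrences.

## What the generator does and does not emulate

The synthetic stack reproduces the *statistical* circumstances of a real
predictor set — spatial smoothness, strong collinearity, two nested
resolutions — but not its physics: no coastlines or nodata structure by
default, no anisotropy, no heavy-tailed variables, and the niche truly is a
product of two Gaussian responses on two principal components, which no real
species obeys. Passing tests therefore demonstrate that the pipeline
recovers known truth under its own generating assumptions and that the
qualitative orderings (specialisation dominates; positional error hurts
specialists; more records help) emerge from the mechanics — not that any
particular real species needs a particular record count.

## Known limitations

* The GAM and MAXENT implementations are penalised-regression formulations;
  backfitting GAMs or the Maxent Java application would differ in detail.
* OCCC against truth depends on probability calibration, hence on the
  prevalence-weighting convention above; rankings (AUC) do not.
* Exact Wilcoxon enumeration is delegated to scipy's exact paths; the
  package only chooses when they apply.
* The low-resolution stack is derived from the high-resolution one by
  bilinear smoothing, so its layers are slightly smoother than an
  independently generated coarse field would be.
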