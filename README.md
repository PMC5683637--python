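# virtualsdm

**Virtual-ecologist benchmarking of presence-background species distribution
models.**

Species distribution models (SDMs) relate species occurrence records to
environmental predictors to map habitat suitability. Every empirical SDM
study faces the same blind spot: the species' true distribution is unknown,
so "performance" can only be scored against the same noisy records the model
was fitted to. `virtualsdm` closes the loop with simulated species whose
niche and range are known exactly. It generates collinear, spatially
autocorrelated environmental raster stacks; defines **virtual species** as
Gaussian niches exp(−x²/2σ²) on the first two (standardised) PCA axes, with
multiplicative suitability and a thresholded true range; samples occurrence
records binomially (a pixel with occurrence probability 0.8 is recorded on
80% of visits) with controlled **sample size** and **positional accuracy**
(coordinates displaced into a k-pixel buffer annulus); fits five
presence-background algorithms (GLM, GAM, GBM, RF, MAXENT) under 5-fold ×
5-background-replicate cross-validation; and scores every run twice:

* **performance** — AUC and the True Skill Statistic (TSS = sensitivity +
  specificity − 1 at the optimised threshold), both "standard" (held-out
  presences vs background) and "independent" (fresh presences and *true*
  absences from the known range);
* **reliability** — spatial agreement of the predicted surface with the true
  suitability, via Schoener's D = 1 − ½Σ|p₁−p₂| on mass-normalised surfaces
  and the concordance correlation OCCC = 2s₁₂/(s₁²+s₂²+(m₁−m₂)²).

The factorial experiment crosses species specialisation (niche breadth σ ∈
{0.8, 0.6, 0.4, 0.2}: generalist → specialist) × algorithm × grid resolution
(factor-4 downscaling) × sample size (5–200) × positional-error level (0–3),
25 runs per cell, and feeds the results table to Wilcoxon comparisons and an
AIC-ranked exp(AUC) factor analysis. The audience is anyone deciding how
many records, at what positional quality, an SDM actually needs — and
whether the evaluation metric they trust can tell them.

## Worked example

```python
import virtualsdm as v

cfg = v.ExperimentConfig(
    species_labels=("generalist", "specialist"),
    algorithms=("GLM",),
    resolutions=("high",),
    sample_sizes=(10, 200),
    precision_levels=(0,),
    n_rows=100, n_cols=100,
    master_seed=1,
)
results = v.run_experiment(cfg)                       # 100 model runs
summary = v.summarize(results, ["species", "sample_size"])
print(summary[["species", "sample_size", "auc_independent_median",
               "occc_truth_median", "schoeners_d_truth_median", "good"]]
      .round(3).to_string(index=False))
```

prints

```
   species  sample_size  auc_independent_median  occc_truth_median  schoeners_d_truth_median  good
generalist           10                   0.744              0.054                     0.092  True
generalist          200                   0.932              0.707                     0.803 False
specialist           10                   0.741              0.222                     0.133  True
specialist          200                   0.910              0.291                     0.365  True
```

Reading the row for the generalist at n = 10: the independent AUC (0.744)
already clears the conventional 0.7 bar for a "good model", yet the
agreement with the true suitability surface is still poor (OCCC 0.054,
D 0.092) — ten records rank habitat correctly long before they reproduce the
actual surface. By n = 200 the generalist's agreement has climbed to
OCCC 0.707 / D 0.803, while the specialist — whose narrow niche is
intrinsically harder to pin down — plateaus much lower (0.291 / 0.365)
despite an equally good AUC (0.910). Note the generalist's `good` flag at
n = 200 is *False*: that flag uses the standard (presence-vs-background)
metrics, which for a widespread species degrade as the background
increasingly overlaps the range. Performance and reliability metrics can
disagree, in both directions — which is the point of measuring both.

The `virtualsdm` command exposes the same pipeline step by step
(`simulate-env`, `make-species`, `sample-occ`, `fit`, `run-experiment`,
`summarize`, `report`).

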