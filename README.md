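# strawsense

Sensory–chemical analysis of strawberry eating quality for breeding programs:
given multi-season trained-panel descriptive ratings (0–10 scale), pooled
fruit chemistry (soluble solids content SSC, titratable acidity TA, pH) and a
GC-MS volatile panel, the package

* fits a **robust Bayesian regression** of panel sweetness on SSC and turns
  the posterior into a **probabilistic sweetness chart** — for any SSC level,
  the probability that a new sample tastes sweeter than average (or lands in
  the top 20% / top 10%);
* fits a **hierarchical varying-slope model** to ask in which harvest month
  SSC is most predictive of perceived sweetness;
* screens **sweetness/flavor-modulating volatiles** with per-season PLS
  models, VIP scores and a cross-season importance index;
* groups samples into **sensory profiles** (PCA + K-means, k = 3);
* decomposes each attribute into **genotype, harvest-month and G×M** effects
  with Bonferroni-corrected −log₁₀ p summaries.

A first-class synthetic-data generator reproduces the statistical structure
of such a trial (56 genotypes × 7 seasons × 2–3 winter harvests, 10–12
panelists, 5 field replicates, ~71 log-normal volatile abundances with
month-dependent presence/absence), so every stage is testable without any
proprietary data.

## The core model

Sweetness ratings contain occasional aberrant samples, so residuals are
modeled as Student-t via a normal scale mixture with per-observation weights:

```
y_i  ~ Normal( β0 + β_ssc · x_i ,  σ²/τ_i )      x_i = SSC (%)
τ_i  ~ Gamma( ν/2 , ν/2 )
β0, β_ssc ~ Normal(0, 10)    ν ~ Uniform(0, 100)    1/σ² ~ Gamma(1, 1)
```

Marginalizing τ gives t(ν) errors; outlying samples receive posterior weights
τ_i < 1 and are automatically down-weighted. The hierarchical extension lets
the slope vary by harvest month j, β_j ~ Normal(μ, σ₁²), with partial pooling
across months. All conditionals are conjugate and sampled by Gibbs; ν is
updated by slice sampling. Convergence is monitored with split-R̂.

The chart converts draws into exceedance probabilities: per draw the
posterior predictive at SSC x is t(ν) with location β0 + β_ssc·x and scale σ,
so P(sweetness > cutoff | x) is a closed-form t tail mass averaged over the
posterior. Cutoffs are the empirical mean and the 80th/90th percentiles of
observed sweetness.

Volatile screening fits one PLS1 model (NIPALS, 5 components) per season on
standardized SSC, TA, sensory firmness and volatiles (pH excluded, collinear
with TA) and scores each predictor with the variable importance in projection
(mean squared VIP = 1). Seasons aggregate into

```
importance index = (#years VIP > 1 with + effect) − (#years VIP > 1 with − effect)
```

bounded by ± the number of seasons; compounds clearing VIP > 1 in at least
two seasons are called influential.

## Worked example

```python
import strawsense as ss

ds, truth = ss.make_fixture("pooled_demo")        # 207 samples, slope 0.45, t5 noise
rf = ds.regression_frame()                        # sweetness vs SSC
data = ss.RegressionData(y=rf["y"].to_numpy(), x=rf["x"].to_numpy())
spec = ss.ModelSpec(kind="pooled", n_chains=3, n_iterations=6500,
                    n_burnin=1500, seed=1)
draws = ss.fit_pooled(data, spec)
summary = ss.summarize(draws, data, seed=1)
chart = ss.make_chart(draws, data.y, data.x)
```

prints, via the summary and chart objects:

```
slope: 0.477 (SD 0.018, 95% CI 0.44-0.51)
average R-hat: 1.001
coverage: 192/207 (92.8%)
 ssc  above_average  top20  top10
 6.0           0.05   0.01   0.01
 6.5           0.10   0.02   0.01
 7.0           0.22   0.04   0.02
 7.5           0.47   0.07   0.04
 8.0           0.74   0.14   0.07
 8.5           0.88   0.31   0.16
SSC for 80% confidence of above-average sweetness: 8.22
```

The posterior slope brackets the generating value 0.45 (one SD ≈ 0.02 at
n = 207); 95% posterior-predictive intervals cover ~93% of samples here
because this fixture deliberately contaminates 5% of records with outliers
the way real panel data do. At SSC 7.5% the chance of above-average sweetness
is roughly a coin flip — exactly where a deterministic least-squares
threshold would declare the fruit "sweet" — and reaching 80% confidence
requires SSC above ~8.2%.

## Command line

```
strawsense --seed 1 --outdir out all           # simulate + every stage
strawsense --seed 1 --outdir out simulate
strawsense --seed 1 --outdir out --dataset out/dataset.csv cluster
strawsense run config.yaml                     # YAML-driven pipeline
```

Every run writes delimited-text outputs plus `manifest.json` with SHA-256
hashes; identical config and seed reproduce identical hashes.

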