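# Methods

This note records the models, the synthetic-data generator that stands in for
a real multi-season sensory/chemistry trial, and the numerical and design
choices made where the design was genuinely open.

## Robust pooled regression

Panel-mean sweetness `y_i` on soluble solids `x_i` (% SSC):

    y_i | β, σ², τ_i ~ Normal(β0 + β_ssc x_i, σ²/τ_i)
    τ_i ~ Gamma(ν/2, rate = ν/2)

with priors Normal(0, variance 10) on β0 and β_ssc, Uniform(0, 100) on ν and
Gamma(1, rate 1) on the precision 1/σ². Marginally the residuals are
Student-t(ν); conditionally everything is conjugate, so the sampler is a
plain Gibbs scheme:

* τ_i | · ~ Gamma((ν+1)/2, (ν + r_i²/σ²)/2), r_i the current residual;
* (β0, β_ssc) | · bivariate normal with observation precisions τ_i/σ² plus
  the prior precision 1/10 on each coefficient;
* 1/σ² | · ~ Gamma(1 + n/2, 1 + Σ τ_i r_i²/2);
* ν | τ by slice sampling (step-out + shrink) of
  n[(ν/2)ln(ν/2) − lnΓ(ν/2)] + (ν/2)Σ(ln τ_i − τ_i) on (0, 100); an
  evaluated-grid inverse-CDF sampler (2 000 log-spaced points) is available
  behind `ModelSpec.nu_sampler="grid"` and agrees with the slice route.

Two readings of the notation were open and are resolved as follows. The
observation variance is σ²/τ (precision scaled by τ), not σ²·τ: only the
former down-weights outliers with τ < 1, which is the behavior the model
exists to produce. Location priors are read as variance 10, not precision 10;
a test verifies that at n ≈ 200 the two readings move the slope posterior by
far less than one posterior SD, so nothing downstream hinges on it.

Defaults: 3 chains, 20 000 iterations with 5 000 burn-in (the analyses in
this repository typically use 5 000–6 500 retained draws per chain, which is
ample at these data sizes — ESS for the slope is in the thousands).
Predictors are deliberately *not* standardized: the slope must stay in
sweetness-points per %-SSC for the chart to be interpretable.

Summaries report split-R̂ per scalar parameter (each chain halved;
R̂ = sqrt(((L−1)/L·W + B/L)/W)). Note that this statistic's floor is
sqrt((L−1)/L), so "identical chains" give R̂ ≈ 1 up to O(1/L), not exactly 1.
Per-observation 95% posterior-predictive intervals use one predictive
replicate per retained draw (fresh τ* ~ Gamma(ν/2, ν/2)); coverage counts
observations inside, and the outlier report counts posterior-mean τ_i < 1.
With small posterior ν the τ-posterior is right-skewed, so substantially more
than the contaminated points can fall marginally below 1; the *ranking* of τ
(contaminated points strictly below the clean median) is the tested, and the
scientifically meaningful, property.

## Hierarchical varying slopes

The slope becomes month-specific, β_j ~ Normal(μ, σ₁²), with β0, σ², ν
shared; μ gets Normal(0, 10) and 1/σ₁² Gamma(1, 1). Extra Gibbs updates are
scalar-normal for β0 and μ, independent normals for the β_j given the rest,
and a gamma update for 1/σ₁². With only ~3 months informing σ₁² its posterior
is prior-dominated; this is expected and harmless for the per-month slopes,
which are data-dominated at ~70 samples/month.

## Probability chart

Cutoffs are the empirical mean ("above average") and the 80th/90th
percentiles ("top 20%"/"top 10%") of the observed panel-mean sweetness; their
provenance is stored in the chart so alternative definitions remain
pluggable. Per draw the posterior predictive at SSC x is t(ν) with location
β0 + β_ssc x and scale σ, so each chart entry is a closed-form t tail mass
averaged over draws — full predictive marginalization, parameter *and*
residual uncertainty. A per-draw τ*-simulation route is kept as the
independent cross-check (`exceedance_by_simulation`) and agrees within
binomial Monte-Carlo error. The grid defaults to 6.0–12.0% in 0.5 steps;
`threshold_ssc` interpolates linearly between grid points and reports an
unreachable confidence as NaN with the maximum attained probability. The
deterministic least-squares line is carried alongside; on symmetric
posteriors its cutoff crossing coincides with the 0.5-probability point of
the Bayesian curve, which the tests assert within grid resolution.

## PLS-VIP screen and importance index

One PLS1 model (NIPALS, deflation per component) per season regresses the
target attribute on SSC, TA, the volatile panel and sensory firmness
(firmness is excluded when it is itself the response; pH is always excluded
as collinear with TA). Predictors and response are standardized within
season — VIP is meaningless across raw scales that span orders of magnitude
(peak areas vs % SSC). Components: 5, capped at the rank limit for small
seasons. Missing volatile cells are zero-filled before standardization
(undetected = below detection). VIP follows

    VIP_j = sqrt( p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a ),  SSY_a = q_a² t_aᵀt_a

so mean squared VIP is 1 by construction (asserted on every fit). The effect
sign is the sign of the final A-component regression coefficient — the
standard convention where no rule is otherwise fixed. The cross-season index
counts signed VIP > 1 hits and is bounded by ± the number of seasons;
"influential" additionally requires hits in ≥ 2 seasons.

## Profile clustering

PCA and K-means run on standardized sensory + SSC/TA/pH variables (the
variable set mixes 0–10 ratings with percentages and pH units). Component
signs are fixed by making each component's largest-magnitude loading
positive. K-means uses 25 restarts with an explicit seed, and clusters are
renumbered by descending mean sweetness of members so "the sweet cluster" is
stable across seeds. Whether the original analysis standardized is unknown;
standardization is the defensible default and `standardize=False` is exposed.

## Effects decomposition

Per season and attribute, Y ~ genotype + month + genotype:month is fitted by
least squares on the finest available observation level — panelist-level
ratings for sensory attributes, field-replicate values for SSC/TA/pH — with
sequential (Type I) sums of squares in that order, matching the classical
`aov` convention; a Type II option exists for unbalanced data (the two
coincide on balanced designs, asserted in tests). Bonferroni correction uses
the family of all testable effects within a season; the family definition is
configuration, not dogma, since the original choice is unstated. Cells
without residual replication are flagged untestable rather than numbered.

## Synthetic-data generator

The generator is the package's stand-in for the real trial and defines the
test conditions:

* design: 56 genotypes, seasons 2009, 2010, 2015–2019, ~12 genotypes per
  season, 2–3 harvests in months 1–3 → ~210 genotype × harvest records;
* SSC = 8.2 + genotype effect (SD 0.9) − 0.6·(month − 1) + noise (SD 0.5),
  so mean SSC declines January → March as in a subtropical fruiting season;
* sweetness = 0.8 + slope(month)·SSC + Σ_k γ_k z_k + σ·t(ν), with z_k
  standardized log(1+abundance) of the active volatiles, σ = 0.3, ν = 5, and
  5% of records contaminated with residuals exceeding 3σ by construction
  (matching the ~5% of samples the robust model down-weights in practice);
  these choices put mean sweetness near 4.2 with a sample range of roughly
  2.5–6 on the 0–10 scale. σ and ν are free parameters of the generator, not
  published values;
* 71 volatiles, log-normal with genotype/month structure, 8 compounds with
  month-declining detection probability (presence/absence variation), 20
  sweetness-active compounds of which 2 reduce sweetness;
* panelist ratings = sample mean + panelist bias (SD 0.5) + noise (SD 0.8);
  replicate chemistry noise SD 0.15 (SSC) — replicate noise intentionally
  much smaller than panel noise, which is why chemistry attributes show
  taller −log p bars than sensory ones in the effects decomposition;
* ratings clip to [0, 10] after noise; the clipped fraction is recorded in
  the ground truth (negligible at the defaults).

What the generator does *not* emulate: panelist psychology (halo effects,
scale drift, serving-order effects), within-sample fruit-to-fruit variation,
correlated volatile families from shared pathways, or measurement-batch
effects. Passing tests therefore demonstrate statistical correctness of the
machinery under the stated structure, not robustness to those artifacts.

One subtlety: sample-level noise shared by all panelists of a sample acts as
a random sample effect, which panelist-level fixed-effects ANOVA cannot
separate from the G×M cell mean (pseudo-replication). The type-I-error
simulation therefore zeroes *all* sample-level effects, including that noise
and the panelist bias, to define a clean null; with real data the
panelist-level F-tests inherit the usual pseudo-replication caveat.

## Problem sizes used in checks

The repository's own checks run at deliberately chosen scales: the
grid-quadrature oracle uses a 6-point fixture with a 101 × 101 × 45 × 40
(β0, β_ssc, σ², ν) grid; recovery uses 10 replicates at n ≈ 207 with 2
chains × 3 000 iterations each; the type-I simulation uses 150–200 small
4-genotype × 2-month designs. These sizes give Monte-Carlo errors well below
the tolerances asserted, with ESS in the thousands for the slope parameters.

## Known limitations

* Exactly two regression models are implemented; there is no general
  probabilistic-programming layer and no model comparison (WAIC/LOO).
* The chart is pooled-only (no per-genotype or per-month charts).
* Importance-index recovery depends on per-season sample size; seasons with
  fewer samples than components fall back to the rank limit and carry less
  evidence.
* Long-format draw exports persist scalar parameters only; per-observation τ
  is summarized (posterior means) rather than stored draw-by-draw.
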