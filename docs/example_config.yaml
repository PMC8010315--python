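# Example pipeline config for `strawsense run`.
# Stages run in dependency order; omit `stages` to run everything.
seed: 1
outdir: strawsense_out
stages: [simulate, cluster, importance, fit-pooled, fit-hier, chart, anova]

# Overrides for the synthetic-data generator (defaults mirror the study
# layout: 56 genotypes, 7 seasons, months 1-3, 71 volatiles).
generator:
  n_genotypes: 56
  outlier_fraction: 0.05

bayes:
  n_chains: 3
  n_iterations: 6500
  n_burnin: 1500

importance:
  attribute: sweetness
  n_components: 5

kmeans:
  k: 3
  n_restarts: 25

chart:
  grid_min: 6.0
  grid_max: 12.0
  grid_step: 0.5
  confidence: 0.8

anova:
  alpha: 0.01
  ss_type: 1
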