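# Demonstration run: simulated 8v8 cohort with anti-correlated 5mC/5hmC
# effects (every planted 5mC shift is coupled to an opposite 5hmC shift of
# half its size), moderate between-sample heterogeneity, RRBS-like
# clustered CpG spacing and overdispersed coverage.
seed: 3
mode: simulate
simulate:
  n_chromosomes: 2
  cpgs_per_chromosome: 400
  spacing: clustered
  n_per_group: 8
  coverage_mean: 30.0
  per_sample_heterogeneity: true
  sample_effect_sd: 0.05
  effects:
    n_5mc_regions: 4
    delta_5mc: 0.3
    n_5hmc_regions: 4
    delta_5hmc: 0.15
    coupling: 0.5     # opposite-sign shift of the other mark, as a fraction of delta
    region_cpgs: 8
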