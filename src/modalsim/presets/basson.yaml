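# Printed disease-outcome parameters used throughout the simulations:
# ileal-histology-like scores, clamped to [0, 80].
groups:
  - name: Dis1
    family: gaussian
    mean: null        # never printed; documented as unavailable
    sd: null
    low: 0
    high: 80
    note: "Crohn's-like group; its mean +/- SD is not printed anywhere, so this entry is a placeholder and is skipped by the loader."
  - name: Dis2
    family: gaussian
    mean: 6.4
    sd: 4.3
    low: 0
    high: 80
  - name: Healthy
    family: gaussian
    mean: 4.5
    sd: 2.5
    low: 0
    high: 80
  - name: DisX
    family: gaussian
    mean: 13.5
    sd: 3.5
    low: 0
    high: 80
    note: "'fake disease X' - a clearly separated disease group"

montecarlo:
  # two-group Monte Carlo power runs: pooled SD 4, N = 63/group,
  # printed true mean differences between the simulated groups
  pooled_sd: 4.0
  n_per_group: 63
  mean_differences:
    dis1_vs_dis2: 1.6
    healthy_vs_dis2: 1.97
    healthy_vs_dis1: 0.42
  n_sims_two_group: 100000
  n_sims_anova: 10000

trio:
  step: 3
  n_max: 63

categorical:
  k_groups: 5
  k_low: 1
  k_high: 6
  n_per_group: [6, 12, 100, 1000]
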