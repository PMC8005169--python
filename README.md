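# modalsim

Simulation and diagnosis of **statistical irreproducibility** under random
sampling and **data multimodality**.

Preclinical studies — the motivating example is human gut-microbiota fecal
transplantation (hGM-FMT) into germ-free rodents — often compare small
groups of donors on a continuous disease outcome (histology or inflammation
scores). When the underlying populations are widely dispersed or split into
severity *subtypes* ("modes"), repeating such a study on freshly sampled
subjects frequently flips both the significance and the *direction* of the
group difference, and recruiting more subjects does not fix it. `modalsim`
is a toolkit for quantifying exactly that, aimed at biostatisticians and
experimentalists who want to stress-test a study design before running it:

* **Samplers** for subject groups: uniform/integer null data, Gaussian
  scores clamped to a bounded scale (`min(max(X, lo), hi)`, with the
  resulting point masses at the bounds preserved), finite Gaussian
  mixtures, and dependent sampling from multimodal targets via a
  random-walk Metropolis–Hastings chain.
* **Trio accumulation**: recruit three donors per group at a time, re-test
  after every trio (N = 3, 6, …, 63), and record the cumulative p-value
  trace, its erratic significance/direction flips, its linearity (R²), and
  the *cumulative probability of a significant simulation* — the chance
  that at least one interim look dips below α.
* **Monte Carlo adjusted significance**: the fraction of 100,000 simulated
  experiments reaching p < α (with exact Clopper–Pearson CI) for a given
  effect size, plus direction-reversal counts, ANOVA families, and null
  categorical experiments for false-discovery counting.
* **Modality diagnostics**: the Hartigan–Hartigan dip statistic
  D = min over unimodal CDFs G of sup |F̂ₙ − G| (bootstrap-calibrated
  against the uniform reference), kernel density estimation with an
  explicit window λ, KDE mode counting, the half-sample mode, and violin
  plots whose densities are bit-identical to the mode-counting KDE.

## Worked example

Simulate the published disease parameters (Dis2: 6.4 ± 4.3 vs Healthy:
4.5 ± 2.5, scores clamped to [0, 80]) as one growing study, then ask how
often such an experiment is significant at all:

```python
from modalsim import (load_preset, run_trio_accumulation,
                      mc_significance_fraction, GroupSpec)

groups = load_preset("basson")["groups"]
trace = run_trio_accumulation(groups["Dis2"], groups["Healthy"],
                              n_max=63, step=3, seed=101)
print(trace.n_values[:5], trace.cumulative_p[:5].round(4))

a = GroupSpec("A", "gaussian", mean=1.97, sd=4.0)
b = GroupSpec("B", "gaussian", mean=0.0, sd=4.0)
s = mc_significance_fraction(a, b, n_per_group=63, n_sims=100_000, seed=1)
print(f"{s.frac_significant*100:.1f}% significant "
      f"(95% CI {s.ci.lower*100:.1f}-{s.ci.upper*100:.1f}%), "
      f"{s.n_direction_reversals} reversed directions")
```

prints

```
[ 3  6  9 12 15] [0.32   0.0682 0.1196 0.0274 0.0303]
78.1% significant (95% CI 77.9-78.4%), 308 reversed directions
```

The trace shows the characteristic erratic behavior: hovering just above
α at N = 6, clearly nonsignificant at N = 9, then significant at N = 12 —
an interim analysis at the wrong moment changes the story. The Monte Carlo
run says that even a true mean difference of 1.97 (SD 4, N = 63/group) is
detected in only ~78% of repeated experiments, and a difference of 0.42 in
~9% — with hundreds of re-runs pointing the *wrong way*.

The same functionality is available from the shell:

```bash
modalsim mc-power --delta 1.97 --sd 4 --n 63 --sims 100000 --seed 101 --out mc.json
modalsim ci 1 38                      # -> 0.1%-13.8% (95% CI)
modalsim dip --input data.csv --boot 2000 --seed 101
modalsim violin --input data.csv --out violin.png
```

## Layout

```
src/modalsim/
  samplers.py     group specs + RNG streams + MCMC
  stats.py        t / Mann-Whitney / ANOVA / Tukey / Kruskal-Wallis /
                  Fisher 2xk / Clopper-Pearson
  trios.py        trio accumulation, patterns, inflections, MxD stabilization
  montecarlo.py   MC significance fractions, categorical null experiments
  modality.py     dip statistic/test, KDE, modes, half-sample mode
  io.py           tidy CSV, YAML configs, presets, JSON reports
  viz.py          violin / trace / time-lapse rendering
  cli.py          `modalsim` command group
  presets/basson.yaml   published group parameters
docs/methods.md   model assumptions, defaults, numerical choices
```
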