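# Methods

## The problem being simulated

A two-group preclinical comparison (e.g., disease vs. healthy donors whose
gut microbiota is transplanted into mice) measures a continuous outcome
per subject — a histology or inflammation score. The population of
subjects is dispersed and often **multimodal**: subjects cluster into
"high", "middle" and "low" responder subtypes. `modalsim` treats the
published group summaries (mean ± SD on a clamped score scale) or an
explicit mixture as the *generative truth*, and studies what repeated
random sampling from that truth does to standard statistical conclusions.

Three questions drive the design:

1. If the same study were re-run on freshly sampled subjects, how often
   would the test be significant, and how often would the effect point
   the other way? (Monte Carlo adjusted significance.)
2. If one study grows by recruiting donors in trios and analysing after
   every trio, how does the p-value trace behave? (Trio accumulation,
   sequential-look inflation.)
3. Is the sample unimodal at all, and if not, where are its modes?
   (Dip test, KDE mode counting.)

## Generative model and samplers

**Clamped Gaussian.** Scores live on a bounded scale, so Gaussian draws
are *clamped*, not resampled: `x = min(max(N(mu, sigma), low), high)`.
Clamping produces point masses at the bounds (a perfectly healthy subject
scores exactly 0); these are intentional and preserved, and the degenerate
constant-sample cases they create downstream are handled by convention
(below) rather than by error.

**Mixtures and dependent sampling.** A population with severity subtypes
is a finite Gaussian mixture. Independent draws select a component by its
weight, then draw from it. For *dependent* sampling — where the next
subject's severity is influenced by the mode the sampler currently
occupies — a random-walk Metropolis–Hastings chain targets the mixture
density. The acceptance ratio is computed in the log domain
(log-sum-exp over components, sigmas strictly positive by construction),
so it remains finite arbitrarily far into the tails. Defaults:
`proposal_scale = 1` outcome unit, `burn_in = 1000`, `thin = 1`, start at
the weighted mixture mean. The proposal scale should be matched to the
mode separation of the target: for widely separated modes (e.g., ±3 with
component SD 0.5) a scale comparable to the separation (3–5 units) is
needed for adequate mode switching; the test suite uses 4 for that
target. Chain quality is assessed by effective sample size; the test
suite checks the first three chain moments against independent mixture
draws within ESS-adjusted Monte Carlo error.

**RNG policy.** One root seed per run; child streams are derived with
`numpy.random.SeedSequence.spawn`, one per group or replicate, so adding
replicates never perturbs earlier ones and every result is bit-reproducible
under its seed. The default seed is 101.

## Statistical tests and conventions

Pooled and Welch t, Mann–Whitney, one-way ANOVA, Tukey HSD,
Kruskal–Wallis, Fisher exact (2×2 and Freeman–Halton 2×k by full
enumeration, k ≤ 5 and total ≤ 250), and the Clopper–Pearson exact
binomial CI. All tests are two-sided and return the effect direction
(sign of mean/median difference) alongside p.

Numerical conventions, chosen so simulation loops never crash on clamped
point-mass data:

* identical constant groups → statistic 0, p = 1 (all tests);
* zero within-group variance with unequal means → p = 0;
* Mann–Whitney: exact tie-aware enumeration when both groups have ≤ 8
  values (the full C(n₁+n₂, n₁) split distribution conditioned on the
  observed ties), tie-corrected normal approximation with continuity
  correction otherwise (the switch point is a module constant);
* Fisher 2×2 two-sidedness by the "sum of probabilities ≤ observed" rule;
* Clopper–Pearson at the boundaries: lower = 0 when successes = 0,
  upper = 1 when successes = trials.

Calibration caveat: exact conditional tests (Fisher) and rank tests on
coarse integer categories at very small n are *conservative* — their null
rejection rate sits below α by construction — so the type-I calibration
checks assert a two-sided ±3 SE band only for the continuous-data tests
at moderate n, and a one-sided (≤ α + 3 SE) bound for the discrete
small-n cases.

## Trio accumulation

A simulated study draws all `n_max` subjects per group once and reveals
prefixes of length `step, 2*step, …, n_max` — accumulation mirrors
recruitment; values are never redrawn between looks. Defaults
`n_max = 63`, `step = 3` give 21 trios and 21 cumulative looks. Per-trio
tests pair trio *i* of group A with trio *i* of group B (matched-index
pairing, 21 pairs).

A study is "significant" if **any** cumulative look falls below α
(the interim-analysis reading); classification by the final look only is
available via `rule="final"`. With 21 looks at a true null, the any-look
significance probability is well above the per-look α — the
sequential-look inflation the trace visualizations are designed to show.
Trace linearity is the OLS R² of cumulative p against N, with a constant
trace defined as R² = 0.

## Mice-per-donor (MxD) stabilization

For one donor tested in 1..`mxd_max` mice, the stabilization point is the
smallest MxD beyond which every running mean stays within ± `band` of the
final running mean. Defaults: `mxd_max = 15`, `band = 1.0` outcome units.
The band is an *absolute* minimally-relevant difference — one point on
the histology scale — rather than a fraction of the group mean, because a
relative band degenerates for groups whose mean sits near the bottom of
the score scale. The sweep extends to 15 ≈ 1.7× the upper end of the
expected stabilization window so late excursions can still disqualify an
early candidate. With the published disease parameters (6.4 ± 4.3,
clamped to [0, 80]) the median stabilization point over 500 replicates is
8, inside the 7 ± 2 window the simulations are expected to show.

## Monte Carlo adjusted significance

`mc_significance_fraction` re-runs the experiment `n_sims` times
(default 10⁵ two-group, 10⁴ ANOVA), each time drawing fresh groups and
applying the chosen test. Reported: fraction significant with its exact
Clopper–Pearson 95% CI, the average observed mean difference, and the
number of simulations whose difference sign opposes the configured true
sign (zero true difference counts no reversals). The two-group fractions
are validated against the closed-form noncentral-t power, and the ANOVA
fractions against noncentral-F, within 3 binomial SE.

The headline two-group runs use **pooled SD 4** with true differences
1.97 and 0.42 at N = 63/group. The printed 57.7% figure for a difference
of 1.6 is not reproducible under any of the stated parameterizations (the
closed form gives ≈ 60.5%), and the printed 67.2% ANOVA fraction depends
on all three group means, which are not all published; both are therefore
documented but not asserted anywhere.

The categorical null experiment draws five identical integer-category
groups (categories 1–6) per iteration and counts omnibus false
discoveries, then compares the observed count against the α-expected
count in a reference batch of 100 iterations by Fisher exact test (the
3/50-vs-5/100 construction).

## Dip statistic and test

The dip is the minimal sup-norm distance between the empirical CDF and
the class of unimodal CDFs, computed by the classic greatest-convex-
minorant / least-concave-majorant iteration over candidate modal
intervals. Bounds: 1/(2n) ≤ D ≤ 1/4. The implementation is validated,
for n ≤ 8 (including tied samples), against an independent brute force
that minimizes the distance over piecewise-linear unimodal CDFs (an atom
allowed at the mode) by linear programming; constant samples return the
lower bound 1/(2n) by convention.

The p-value is Monte Carlo: the fraction of `n_boot` (default 2000)
uniform(0,1) samples of the same n whose dip meets or exceeds the
observed one — the uniform distribution being the least-favorable
unimodal reference. Bootstrap calibration was chosen over published
critical-value tables because it is transparent, seedable and exact at
any n; the cost is Monte Carlo granularity of order 1/`n_boot` in the
p-value. The inner loop is JIT-compiled with numba when available, with a
pure-Python fallback producing identical values.

## KDE, modes, half-sample mode

Gaussian (default) or Epanechnikov kernels on an explicit grid
(512 points, padded by 4 bandwidths); the density is renormalized to
integrate to 1 over the grid by the trapezoid rule. "auto" bandwidth is
Silverman's rule `0.9 min(sd, IQR/1.34) n^(-1/5)`, falling back to 1.0
outcome unit for dispersion-free samples. Modes are strict local maxima
of the gridded density filtered by prominence ≥ `min_prominence` × max
density (default 0.05, suppressing grid noise); the global maximum always
survives the filter. The half-sample mode repeatedly keeps the shortest
interval containing ⌈n/2⌉ points until ≤ 3 remain and returns their mean,
with ties resolved toward the lower interval (deterministic).

Violin plots are drawn from the same `kde` function the mode statistics
use — the test suite asserts the arrays are identical — and all plot
jitter derives from the run seed, so figures are reproducible.

## What the synthetic data does and does not emulate

The generators reproduce the *published summary parameters* (means, SDs,
clamp bounds, category ranges) and the sampling designs (trio
recruitment, fixed N re-runs, dependent multimodal sampling). They do not
emulate cage-clustering or other intraclass correlation, batch effects,
sex differences, measurement error on the score scale, or non-Gaussian
skew within a severity mode ("asymmetrical" subtype shapes are not
modelled; mixture components are symmetric Gaussians). Passing tests
therefore demonstrate properties of random sampling and multimodality
per se, not of any particular laboratory workflow.

One published group (the first disease group, "Dis1") has no printed
mean ± SD anywhere; the preset ships it as an explicitly unavailable
placeholder and every quantitative check uses only the printed groups.
Problem sizes in the test suite (e.g., 2000–3000 null replicates for
calibration, 300–500 bootstrap replicates for dip checks, 10⁵ simulations
for the headline fractions) were chosen as the package's own balance
between Monte Carlo resolution and suite runtime.

## Known limitations

* The Freeman–Halton enumeration is exponential in k and the margins;
  the guard (k ≤ 5, total ≤ 250) reflects the intended use on
  false-discovery count tables, not general contingency analysis.
* The dip test's Monte Carlo p-value inherits 1/`n_boot` granularity;
  p-values below 1/`n_boot` are reported as 0.
* No group-sequential alpha-spending corrections are provided: the point
  of the trace engine is to *exhibit* sequential-look inflation, not to
  correct it.
* MCMC output is serially dependent by design; treat chain draws as a
  sample only after checking ESS, and expect location tests on chain
  output to be anticonservative relative to independent draws.
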