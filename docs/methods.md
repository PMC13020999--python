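# Methods

## Task model

A session is a sequence of two-armed bandit games. Payoffs are Gaussian
with SD 8 points, rounded to integers and clamped to [1, 100] (the display
shows integer points in that range; clamping is the simplest bounding
rule). One bandit mean is anchored at 40 or 60 (uniform side); the other
differs by 4, 8, 12, or 20 points, direction uniform, with the sign flipped
in the single case (anchor 40, difference 20) that would otherwise put both
means on anchors. The four forced trials realize the information condition:
[2 2] (a uniform ordering of two plays per side) or [1 3] (uniform singleton
side and position). A game has 1 or 6 free choices (the horizon).

Default session: 156 games of which 65 are repeated pairs (130 games) and
26 unpaired — matching the task's average session (~154 games, ~65 pairs).
Pair members share every stimulus field bit-for-bit and are separated by at
least `min_pair_separation = 10` intervening games, our operationalization
of "separated by several minutes" at roughly 9 s/game; scheduling is a
random permutation with local swap repair, failing loudly if the separation
constraint is infeasible. Conditions are counterbalanced by dealing pairs
round-robin across horizon × information × mean-difference cells and
filling with unpaired games into the smallest horizon × information cell,
so cell counts differ by at most one whenever divisibility allows.

Unpaired games are retained in model fitting, each with its own latent
frozen-noise draw. Games whose forced-trial means tie are excluded from
p(low mean) and from the pure-random mixture (low mean is undefined there).

## Choice model

First free choice: right iff `dR + A·dI + b + n_det + n_ran > 0`, with
`n_det` frozen per pair (drawn lazily at the pair's first appearance, so
presentation order cannot change pair-level draws) and `n_ran` fresh per
play. Both noises are logistic; σ parameters are logistic **scales**
(SD = σ·π/√3). The original model family is ambiguous about scale vs SD;
we standardize on scale and provide `SubjectParams.from_sd` and a
`sigma_is_sd` fitting flag for the SD convention. Marginalizing `n_ran`
gives `P(right) = expit((dR + A·dI + b + n_det)/σ_ran)`; with `σ_ran = 0`
the rule is a hard threshold and an exact tie is resolved by a fair coin
from the session RNG.

Later free choices of horizon-6 games are not analyzed by any statistic
here; the simulator fills them with a declared greedy-on-sample-means
policy (same σ_ran logistic noise, bias b) and flags them `analysis = 0`.

## Model-free statistics

Per subject × horizon: `p(low mean)` over [2 2] games, `p(high info)` over
[1 3] games, and `p(inconsistent)` over complete repeated pairs. The
pure-deterministic prediction for p(inconsistent) is exactly 0; the
pure-random prediction is the occupancy-weighted mixture of `2p(1−p)` over
(dR, I) strata.

Two estimator details matter at per-subject sample sizes:

* **Strata.** Conditioning is on (dR, I) up to left-right mirror symmetry,
  which maps (dR, dI) → (−dR, −dI): [2 2] games are binned by |dR|, [1 3]
  games by the *signed* product dR·dI (the reward advantage of the more
  informative option). Sign pooling within [1 3] would be wrong whenever
  the information bonus is nonzero. Four quantile bins per condition by
  default (`n_bins`); stratum probabilities are estimated per subject.
* **Bias correction.** The plug-in `2p̂(1−p̂)` is biased low by `2·Var(p̂)`,
  which at ~10 rows per stratum is comparable to the effect being tested.
  The default estimator applies the `n/(n−1)` unbiasing factor per stratum,
  clipped at the analytic bound 1/2 (`bias_corrected=False` recovers the
  plug-in).

Horizon contrasts are two-sided paired t-tests; a zero-variance nonzero
difference is flagged degenerate. The exclusion rule keeps a subject iff
their 10th-trial accuracy in horizon-6 games (against the generative means,
taken from the optional `mean_left/mean_right` columns or estimated from
observed rewards) beats chance in a one-sided exact binomial test at
p < 0.001.

## Hierarchical model and priors

Per horizon i and subject s: `A_is ~ Gaussian(μ_A, σ_A)`,
`b_is ~ Gaussian(μ_b, σ_b)`, `σ_det,is ~ Gamma(k_det, λ_det)`,
`σ_ran,is ~ Gamma(k_ran, λ_ran)` — Gamma in shape/**rate** form (mean k/λ).
Default hyperpriors: `μ ~ Gaussian(0, 100)` (second parameter an SD; a flag
reinterprets it as precision), `σ_A, σ_b ~ Exponential(0.01)`,
`k ~ Exponential(0.01)`, `λ ~ Exponential(10)`. A narrower published
variant (Gaussian SD 10, Exponential(0.1)) is available via
`HyperPriorConfig.narrow()`. The frozen noise enters as one explicit latent
per pair (and per unpaired game) with prior `Logistic(0, σ_det,is)` —
mirroring the graphical-model formulation rather than marginalizing by
quadrature; the quadrature marginal is provided as a cross-check utility
(`marginal_pair_likelihood`).

Variants: `sigma_by_info` (σ per information condition), `variance_dI`
(dI = difference of forced-reward population variances, right − left;
single-observation sides have variance 0), `no_det` / `no_ran` (reduced
one-noise models; `no_ran` uses the hard-threshold likelihood and returns
−∞ for impossible choices), `det_fixed_across_horizon` /
`ran_fixed_across_horizon` (noise shared across horizons).

## Sampler

A vectorized blocked Metropolis-within-Gibbs sampler (all chains advance as
one numpy axis). Blocks: latent frozen-noise values (random-walk MH per
unit), subject parameters (per-parameter MH; σ on the log scale with
Jacobian), conjugate Gibbs for group means, MH for group SDs, and
shape/rate/ridge moves for the Gamma hyperparameters. Hierarchical scale
parameters form funnels in which centered updates stall; the sampler
interweaves non-centered moves — joint mean shifts, group-SD rescalings of
the centered deviations, joint rescaling of a subject's σ_det with its
latents, and a group-level scale move coupling all subject σ with the
Gamma rate (and latents). Proposal scales adapt toward 0.44 acceptance
during burn-in only. Determinism: a master seed fully determines all
chains; identical configuration reproduces draws bit-for-bit.

Correctness was established by (i) exact recovery of closed-form priors in
prior-only models (free and pinned hyperparameters), (ii) agreement of toy
posterior means with dense-grid quadrature within 2%, and (iii) agreement
of the likelihood's marginal pair statistics with Monte-Carlo simulation.

Reference sampling settings mirror the published fits (10 chains × 5000
kept, 5000 burn-in, thin 1); validation experiments in this package use
reduced settings (typically 3–4 chains × 600–1000 kept after equal
burn-in), which the convergence diagnostics justify for the group-level
quantities of interest. Convergence is operationalized as split-R̂ < 1.1
for every scalar parameter plus bulk ESS > 400 (via arviz) for group-level
parameters.

## Derived summaries

Per draw, the group-level noise scale is the Gamma mean k/λ per horizon.
Derived: det_fraction = σ_det²/(σ_det²+σ_ran²) per horizon and pooled
(mean of the two horizons' group means — the headline number), horizon
ratios σ(H6)/σ(H1) per noise type, and P(σ(H6) > σ(H1)). A noise scale
shared across horizons has an undefined ratio, reported as such.

## Validation designs

* **Parameter recovery** (default design): 65 subjects, noise-scale truths
  evenly spanning 0–10 (independently permuted per noise type and horizon,
  so the two are uncorrelated), A ~ N(1, 2), b ~ N(0, 1), one default
  session per subject, reduced MCMC (4 × 1000 kept / 1000 burn-in).
  Recovered values are subject-level posterior means; we report Pearson r,
  through-origin slopes, and biases.
* **Zero-noise controls**: one component exactly zero, 32 subjects;
  "concentrated near zero" is operationalized as the absent component's
  group mean posterior mean < 1 point and < 1/4 of the present component's.
* **Shuffled control**: ground truths are best-fit values independently
  permuted across subjects per noise type (shared across horizons so a
  pseudo-subject keeps a coherent horizon pair); the four cross-type
  correlations are tested as a joint null at α = 0.05 with a Bonferroni
  per-test threshold.
* **Reduced-model detection**: four generators crossing which noise type is
  horizon-dependent, at fitted-human magnitudes (σ_det 1.7→4.3, σ_ran
  4.6→11.7 when dependent; ~×2.5 horizon ratio and ~14% frozen share),
  65 subjects, multiplicative truth jitter 0.25. Detection = P(increase)
  > 0.95; presence = P(group σ > 0.5) > 0.95.
* **Posterior predictive checks**: replicates draw one posterior sample of
  all subject parameters and replay the subjects' identical game sequences
  (first free choices only — later trials feed no statistic); bands are the
  2.5–97.5 percentiles over replicates.

## What the synthetic data do and do not show

The generator reproduces the task's stimulus statistics, session
composition, and the two-noise choice process, so passing tests establish
that the pipeline is internally correct: the statistics estimate what they
claim, the sampler targets the stated posterior, and the decomposition
recovers generative parameters in the regimes tested. Synthetic agents do
not learn, drift, lapse, or carry deterministic structure *across* games,
and their frozen noise is exactly logistic and exactly stable — real
participants may violate any of these, so recovery quality here is an
upper bound on what to expect from human data. The study's real-data
headline estimates (e.g. a ~14% frozen-noise share and specific group
means) depend on participant data that are not distributed and are used
here only to set realistic magnitudes for generators.

A known divergence: the published recovery experiments report a ~32%
underestimation of σ_det (through-origin slope ≈ 0.68) alongside a
near-unit σ_ran slope. Our implementation, validated against independent
oracles and run to convergence, shows only a mild σ_det underestimation
under the 0–10 grid design (slope ≈ 0.92–0.96) and reproduces the strong
σ_ran/σ_det correlation asymmetry only under fitted-magnitude truth
distributions (where the σ_ran correlations match the published 0.91/0.84
almost exactly). The published truth-generating settings are not stated;
we report our results under the declared designs rather than tuning either
toward the printed values.

## Numerical choices

Logistic log-densities use the |x| form to avoid overflow; σ proposals are
floored at 1e-12; Gamma log-densities tolerate zero arguments (rejected via
−∞). Quadrature over a latent logistic uses the substitution
n = σ·logit(u) with Gauss–Legendre nodes on (0, 1). Grid oracles integrate
over a 3-D parameter grid chunked along one axis to bound memory. Child
seeds derive from `SeedSequence([master, stage])` with fixed stage indices;
per-subject simulation streams are spawned from the stage sequence.

## Problem sizes

Validation experiments are sized for a single CPU: the acceptance script's
recovery uses the full 65-subject design (~1 min); the test suite runs
recovery and shuffled controls at 65 subjects with 4 × 800–1000 samples,
detection at 65 subjects × 4 scenarios, zero-noise controls at 32
subjects, and posterior predictive checks at 16 subjects × 40 replicates.
These sizes are the package's declared experimental conditions; enlarging
them (toward the reference 10 × 5000 sampling) changes Monte-Carlo error,
not conclusions.
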