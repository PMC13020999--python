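# dualnoise

**Separating frozen (stimulus-driven) and random decision noise in
explore–exploit choices.**

Behavioral variability in explore–exploit tasks is usually summarized as a
single "decision noise" term. But variability measured that way confounds
two very different things: a *deterministic* response to stimulus features
the model does not capture, and genuinely *random* (non-stimulus-driven)
variability. `dualnoise` implements the repeated-games Horizon Task
analysis that separates the two: if the exact same game — same forced
plays, same outcomes — is presented twice without the participant noticing,
a purely stimulus-driven chooser answers identically both times, while a
purely random chooser agrees only at chance.

The package is aimed at computational cognitive modellers: it simulates the
task and a generative two-noise chooser, computes the model-free
consistency statistics with their analytic bounds, fits a hierarchical
Bayesian model that performs the decomposition, and ships the validation
battery (parameter recovery, shuffled and zero-noise controls,
reduced-model detection, posterior predictive checks).

## The model

On the first free choice of a game the chooser forms

```
dQ = dR + A*dI + b + n_det + n_ran
```

and picks the right bandit iff `dQ > 0`. Here `dR` is the difference in mean
forced-trial rewards (right − left), `dI ∈ {−1, 0, +1}` the information
difference in the [1 3] condition, `A` the information bonus, `b` a spatial
bias. The two noise terms are zero-mean logistic: `n_det ~ Logistic(0, σ_det)`
is **frozen** — drawn once per repeated game pair, identical on both
presentations — while `n_ran ~ Logistic(0, σ_ran)` is drawn fresh on every
play. σ values are logistic *scales* (SD = σ·π/√3).

Within-pair choice consistency bounds the decomposition: a frozen-noise-only
agent has `p(inconsistent) = 0`; a random-noise-only agent reaches the
mixture bound `p(inconsistent) = Σ ρ(dR,I) · 2p(1−p)` with
`p = p(low mean | dR, I)`. In between, the hierarchical model — Gaussian
group priors on `A`, `b`; Gamma(shape k, rate λ) group priors on σ; one
explicit latent `n_det` per pair — estimates `σ_det` (a lower bound on
stimulus-driven noise) and `σ_ran` (an upper bound on true randomness) per
subject and horizon, and the derived fraction
`σ_det² / (σ_det² + σ_ran²)`.

Inference is a vectorized blocked Metropolis-within-Gibbs sampler
(`dualnoise.mcmc`) with interweaved non-centered moves for the hierarchical
scale parameters, validated against closed-form priors and a dense-grid
quadrature oracle.

## Worked example

```python
import numpy as np, pandas as pd
from dualnoise import (TaskConfig, MCMCConfig, simulate_cohort,
                       first_free_choices, subject_stats, derived_summaries)
from dualnoise.validation import fit_cohort

# 12 simulated subjects; noise and information bonus grow with horizon
rng = np.random.default_rng(1)
truths = pd.DataFrame([
    dict(subject_id=f"s{s:02d}", horizon=h, A=rng.normal(a, 1),
         b=rng.normal(0, 1), sigma_det=rng.gamma(2, sd/2),
         sigma_ran=rng.gamma(2, sr/2))
    for h, (a, sd, sr) in {1: (1.0, 1.5, 4.0), 6: (4.0, 3.5, 9.0)}.items()
    for s in range(12)
])
trials, _ = simulate_cohort(truths, TaskConfig(), seed=1)
stats = subject_stats(first_free_choices(trials))
print(stats.groupby("horizon")[["p_low_mean", "p_inconsistent_22",
                                "predicted_inconsistent_random_22"]].mean().round(3))
```

prints (seed 1):

```
         p_low_mean  p_inconsistent_22  predicted_inconsistent_random_22
horizon
1             0.152              0.147                             0.194
6             0.234              0.251                             0.303
```

Both variability (`p_low_mean`) and pair inconsistency rise from horizon 1
to 6 — more exploration when it is worth more — and inconsistency stays
*below* the pure-random bound in both horizons: a share of the "noise" is
frozen to the stimulus. Fitting the hierarchical model
(`fit_cohort(trials, MCMCConfig(...))` followed by `derived_summaries`)
turns that gap into a posterior over `σ_det² / (σ_det² + σ_ran²)` per
horizon; see `examples/03_hierarchical_fit.py`.

The `examples/` directory walks through each capability: task simulation,
model-free statistics, hierarchical fitting, parameter recovery, and
posterior predictive checks. A thin CLI (`dualnoise simulate | analyze |
fit | recover | ppc | controls | pipeline`) wraps the same library calls.

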