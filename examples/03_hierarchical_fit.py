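"""Fit the hierarchical two-noise model and read off the noise decomposition.

Subject-level parameters (A, b, sigma_det, sigma_ran) per horizon sit under
Gaussian / Gamma group priors; the frozen noise of each repeated pair is an
explicit latent variable.  The derived quantity det_fraction =
sigma_det^2 / (sigma_det^2 + sigma_ran^2) says how much of the decision
noise is stimulus-driven.
"""

import numpy as np
import pandas as pd

from dualnoise import (
    MCMCConfig, TaskConfig, convergence_check, derived_summaries,
    first_free_choices, simulate_cohort,
)
from dualnoise.validation import fit_cohort

rng = np.random.default_rng(2)
recs = []
for h, (A, sd, sr) in {1: (1.0, 1.5, 4.0), 6: (4.0, 3.0, 8.0)}.items():
    for s in range(16):
        recs.append(dict(subject_id=f"s{s:02d}", horizon=h, A=rng.normal(A, 1),
                         b=rng.normal(0, 1), sigma_det=rng.gamma(3, sd / 3),
                         sigma_ran=rng.gamma(3, sr / 3)))
truths = pd.DataFrame(recs)
trials, _ = simulate_cohort(truths, TaskConfig(), seed=2)

draws = fit_cohort(trials, MCMCConfig(chains=4, samples=800, burnin=800, seed=2))
report = convergence_check(draws)
print(f"convergence: max split-R-hat = {report.table['rhat'].max():.3f} "
      f"(pass: {report.passed})")

der = derived_summaries(draws)
print(der.summary().round(3).to_string(index=False))
print("\ndet_fraction_pooled is the share of choice variability frozen to "
      "the stimulus; ratio_*_h6_h1 > 1 means that noise type grows when "
      "exploration becomes valuable.")
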