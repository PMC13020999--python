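"""Convergence diagnostics: split-R-hat and effective sample size.

The study eyeballed chain convergence; here that is operationalized as
split-R-hat < 1.1 for every sampled quantity plus bulk ESS > 400 for the
group-level hyperparameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mcmc import GROUP_PARAMS, PosteriorDraws

__all__ = ["split_rhat", "convergence_check", "ConvergenceReport"]


def split_rhat(x: np.ndarray) -> np.ndarray:
    """Classic split-R-hat for draws shaped (..., chains, draws).

    Each chain is split in half; R-hat compares between- and within-half
    variance: ``sqrt(((N-1)/N * W + B/N) / W)``.  Constant chains give 1.
    """
    x = np.asarray(x, dtype=float)
    c, n = x.shape[-2], x.shape[-1]
    if n < 4:
        raise ValueError("need at least 4 draws per chain")
    half = n // 2
    halves = np.concatenate(
        [x[..., :half], x[..., half : 2 * half]], axis=-2
    )  # (..., 2c, half)
    means = halves.mean(axis=-1)
    w = halves.var(axis=-1, ddof=1).mean(axis=-1)
    b = half * means.var(axis=-1, ddof=1)
    var_plus = (half - 1) / half * w + b / half
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sqrt(var_plus / w)
    return np.where(w == 0, np.where(b == 0, 1.0, np.inf), r)


@dataclass
class ConvergenceReport:
    table: pd.DataFrame
    passed: bool
    limited: bool = False  # single chain: diagnostics only partially valid

    def __repr__(self) -> str:  # pragma: no cover
        worst = self.table.sort_values("rhat", ascending=False).head(5)
        return (
            f"ConvergenceReport(passed={self.passed}, "
            f"max_rhat={self.table['rhat'].max():.4f})\n{worst}"
        )


def convergence_check(
    draws: PosteriorDraws,
    rhat_threshold: float = 1.1,
    ess_threshold: float = 400.0,
) -> ConvergenceReport:
    """Split-R-hat for every scalar parameter and bulk ESS (via arviz) for
    the group-level hyperparameters; passes iff all R-hat values are below
    the threshold and every group-level ESS exceeds its floor."""
    import arviz as az

    flat = draws.flat()
    names = list(flat)
    stacked = np.stack([flat[n] for n in names])  # (P, C, D)
    rhats = split_rhat(stacked)

    ess = {}
    for name in names:
        if name.split("[")[0] in GROUP_PARAMS:
            ess[name] = float(az.ess(np.asarray(flat[name]), method="bulk"))

    table = pd.DataFrame(
        {
            "parameter": names,
            "rhat": rhats,
            "ess": [ess.get(n, np.nan) for n in names],
            "group_level": [n.split("[")[0] in GROUP_PARAMS for n in names],
        }
    )
    limited = draws.chains < 2
    ok_rhat = bool(np.all(table["rhat"] < rhat_threshold))
    group_ess = table.loc[table["group_level"], "ess"]
    ok_ess = bool((group_ess > ess_threshold).all()) if len(group_ess) else True
    return ConvergenceReport(
        table=table, passed=(ok_rhat and ok_ess and not limited), limited=limited
    )
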