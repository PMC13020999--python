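"""Derived posterior quantities.

From the group-level Gamma hyperparameters of each noise type the per-draw
group mean noise scale is k/lam.  Derived from it:

* ``det_fraction`` — sigma_det^2 / (sigma_det^2 + sigma_ran^2), the share of
  choice variability attributable to the frozen, stimulus-driven component
  (the paper-style headline number pools the two horizons' group means);
* horizon ratios sigma(H6)/sigma(H1) per noise type; and
* tail probabilities P(sigma(H6) > sigma(H1)), the evidence that a noise
  component grows when exploration becomes more valuable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mcmc import PosteriorDraws

__all__ = ["DerivedPosterior", "derived_summaries", "det_fraction"]


def det_fraction(m_det: np.ndarray, m_ran: np.ndarray) -> np.ndarray:
    """sigma_det^2 / (sigma_det^2 + sigma_ran^2), elementwise; 0 when both are 0."""
    m_det = np.asarray(m_det, dtype=float)
    m_ran = np.asarray(m_ran, dtype=float)
    tot = m_det**2 + m_ran**2
    with np.errstate(invalid="ignore", divide="ignore"):
        out = m_det**2 / tot
    return np.where(tot == 0, 0.0, out)


def _per_horizon_mean(draws: PosteriorDraws, which: str):
    """Group mean noise scale per horizon: dict horizon -> (C, D) draws.

    Slots split by information condition are averaged; a noise scale shared
    across horizons maps to every horizon (its ratio is then undefined).
    """
    labels = {
        "det": draws.posterior.slotd_labels,
        "ran": draws.posterior.slotr_labels,
    }[which]
    m = draws.group_noise_mean(which)  # (C, D, slots)
    horizons = draws.posterior.horizons
    shared = all(h is None for h, _ in labels)
    out = {}
    for hi, h in enumerate(horizons):
        cols = [
            j for j, (hh, _) in enumerate(labels) if (hh == hi or hh is None)
        ]
        out[h] = m[:, :, cols].mean(axis=2)
    return out, shared


@dataclass
class DerivedPosterior:
    det_fraction_pooled: np.ndarray  # (C, D)
    det_fraction_by_horizon: dict
    ratio_det: np.ndarray | None
    ratio_ran: np.ndarray | None
    p_increase_det: float | None
    p_increase_ran: float | None
    group_mean_det: dict
    group_mean_ran: dict

    def summary(self) -> pd.DataFrame:
        """Posterior means and central 95% intervals of all derived draws."""

        def row(name, arr):
            if arr is None:
                return dict(quantity=name, mean=np.nan, lo2_5=np.nan, hi97_5=np.nan)
            a = np.asarray(arr).ravel()
            return dict(
                quantity=name,
                mean=float(a.mean()),
                lo2_5=float(np.percentile(a, 2.5)),
                hi97_5=float(np.percentile(a, 97.5)),
            )

        rows = [row("det_fraction_pooled", self.det_fraction_pooled)]
        for h, arr in self.det_fraction_by_horizon.items():
            rows.append(row(f"det_fraction_h{h}", arr))
        rows.append(row("ratio_det_h6_h1", self.ratio_det))
        rows.append(row("ratio_ran_h6_h1", self.ratio_ran))
        for h, arr in self.group_mean_det.items():
            rows.append(row(f"group_sigma_det_h{h}", arr))
        for h, arr in self.group_mean_ran.items():
            rows.append(row(f"group_sigma_ran_h{h}", arr))
        df = pd.DataFrame(rows)
        extra = pd.DataFrame(
            [
                dict(quantity="p_increase_det", mean=self.p_increase_det,
                     lo2_5=np.nan, hi97_5=np.nan),
                dict(quantity="p_increase_ran", mean=self.p_increase_ran,
                     lo2_5=np.nan, hi97_5=np.nan),
            ]
        )
        return pd.concat([df, extra], ignore_index=True)


def derived_summaries(draws: PosteriorDraws) -> DerivedPosterior:
    """Compute the derived noise-decomposition posterior from MCMC draws.

    Requires both noise types in the fitted model; the horizon ratio of a
    noise shared across horizons is reported as undefined (None).
    """
    post = draws.posterior
    if not (post.include_det and post.include_ran):
        raise ValueError("derived summaries need both noise components")
    md, det_shared = _per_horizon_mean(draws, "det")
    mr, ran_shared = _per_horizon_mean(draws, "ran")
    horizons = post.horizons

    pooled_det = np.mean([md[h] for h in horizons], axis=0)
    pooled_ran = np.mean([mr[h] for h in horizons], axis=0)
    frac_pooled = det_fraction(pooled_det, pooled_ran)
    frac_h = {h: det_fraction(md[h], mr[h]) for h in horizons}

    ratio_det = ratio_ran = None
    p_inc_det = p_inc_ran = None
    if len(horizons) == 2:
        h1, h6 = horizons
        if not det_shared:
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio_det = md[h6] / md[h1]
            p_inc_det = float((md[h6] > md[h1]).mean())
        if not ran_shared:
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio_ran = mr[h6] / mr[h1]
            p_inc_ran = float((mr[h6] > mr[h1]).mean())
    return DerivedPosterior(
        det_fraction_pooled=frac_pooled,
        det_fraction_by_horizon=frac_h,
        ratio_det=ratio_det,
        ratio_ran=ratio_ran,
        p_increase_det=p_inc_det,
        p_increase_ran=p_inc_ran,
        group_mean_det=md,
        group_mean_ran=mr,
    )
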