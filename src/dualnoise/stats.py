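"""Model-free exploration and consistency statistics.

Working on first-free-choice rows (see :func:`dualnoise.task.first_free_choices`),
this module computes, per subject and horizon:

* ``p(low mean)`` — probability of picking the lower forced-trial mean in the
  equal-information ("22") games: the model-free index of behavioral
  variability / random exploration;
* ``p(high info)`` — probability of picking the once-played option in the
  unequal-information ("13") games: the index of directed exploration;
* ``p(inconsistent)`` — fraction of repeated game pairs whose two first free
  choices differ, bounded below by 0 (purely frozen, stimulus-driven noise)
  and above by the pure-random prediction
  ``sum_strata rho * 2 p (1 - p)`` where p is the stratum-wise p(low mean)
  and rho the stratum occupancy among pairs.

It also provides the paired-t horizon contrast and the performance-based
participant exclusion rule (above-chance accuracy on the last choice of
horizon-6 games at p < 0.001, one-sided exact binomial).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._exceptions import UndefinedStatisticError
from .task import validate_trials

__all__ = [
    "p_low_mean",
    "p_high_info",
    "p_inconsistent",
    "pure_random_prediction",
    "subject_stats",
    "horizon_contrast",
    "HorizonContrast",
    "exclude_subjects",
    "PURE_DETERMINISTIC_PREDICTION",
]

#: Purely frozen (deterministic) noise repeats the same choice: inconsistency 0.
PURE_DETERMINISTIC_PREDICTION = 0.0


def _eligible(rows: pd.DataFrame, horizon: int, info: str) -> pd.DataFrame:
    out = rows[(rows["horizon"] == horizon) & (rows["info_condition"] == info)]
    return out


def p_low_mean(rows: pd.DataFrame, horizon: int) -> float:
    """Fraction of equal-information games choosing the lower forced mean."""
    sub = _eligible(rows, horizon, "22")
    flags = sub["chose_low_mean"].dropna()
    if len(flags) == 0:
        raise UndefinedStatisticError(
            f"no eligible [2 2] rows with unequal forced means at horizon {horizon}"
        )
    return float(flags.astype(bool).mean())


def p_high_info(rows: pd.DataFrame, horizon: int) -> float:
    """Fraction of unequal-information games choosing the once-played option."""
    sub = _eligible(rows, horizon, "13")
    flags = sub["chose_high_info"].dropna()
    if len(flags) == 0:
        raise UndefinedStatisticError(f"no [1 3] rows at horizon {horizon}")
    return float(flags.astype(bool).mean())


def _complete_pairs(rows: pd.DataFrame) -> pd.DataFrame:
    paired = rows[rows["pair_id"].astype(str).str.len() > 0]
    counts = paired.groupby(["subject_id", "pair_id"])["game_id"].transform("size")
    return paired[counts == 2]


def p_inconsistent(rows: pd.DataFrame, horizon: int, info_condition: str) -> float:
    """Fraction of complete repeated pairs whose first free choices differ."""
    sub = _complete_pairs(_eligible(rows, horizon, info_condition))
    if len(sub) == 0:
        raise UndefinedStatisticError(
            f"no complete pairs at horizon {horizon}, info {info_condition}"
        )
    differs = sub.groupby(["subject_id", "pair_id"])["chose_right"].nunique() == 2
    return float(differs.mean())


def _stratum_variable(rows: pd.DataFrame) -> pd.Series:
    """The conditioning variable for p(low mean | dR, I) strata.

    Left-right mirror symmetry maps (dR, dI) to (-dR, -dI) and leaves
    p(low mean) unchanged, so mirror images may share a stratum.  In "22"
    games (dI = 0) that collapses to |dR|; in "13" games the signed product
    dR*dI (reward advantage of the more informative side) is the mirror
    invariant — and it must stay signed, because an information bonus makes
    p(low mean) depend on whether reward and information point the same way.
    """
    dr = rows["delta_R"].astype(float)
    di = rows["delta_I"].astype(float)
    return (dr * di).where(di != 0, dr.abs())


def _strata_bins(x: pd.Series, n_bins: int) -> pd.Series:
    """Quantile bins of the stratum variable; equal values always share a
    bin so the two members of a pair cannot be split."""
    if x.nunique() < 2 or n_bins <= 1:
        return pd.Series(0, index=x.index)
    return pd.qcut(x, min(n_bins, x.nunique()), labels=False, duplicates="drop")


def pure_random_prediction(
    rows: pd.DataFrame,
    horizon: int,
    info_condition: str,
    n_bins: int = 4,
    bias_corrected: bool = True,
) -> float:
    """Expected p(inconsistent) if all noise were per-play random noise.

    Within each (dR, I) stratum the two choices of a pair would be
    independent with the stratum's p = p(low mean | stratum), giving conditional
    inconsistency 2p(1-p); strata are mixed by their occupancy rho among
    complete pairs.  Tied-mean games are excluded (low mean undefined).

    The plug-in 2p̂(1-p̂) underestimates 2p(1-p) by 2 Var(p̂); the n/(n-1)
    finite-sample correction removes that bias, which otherwise dominates
    the comparison at per-subject stratum sizes.
    """
    sub = _eligible(rows, horizon, info_condition)
    sub = sub[sub["chose_low_mean"].notna()].copy()
    if len(sub) == 0:
        raise UndefinedStatisticError("no rows with defined low-mean choice")
    sub["stratum"] = _strata_bins(_stratum_variable(sub), n_bins)

    pairs = _complete_pairs(sub)
    if len(pairs) == 0:
        raise UndefinedStatisticError("no complete pairs to weight strata")
    # one stratum value per pair (members share |dR| by construction)
    pair_strata = pairs.groupby(["subject_id", "pair_id"])["stratum"].first()
    rho = pair_strata.value_counts(normalize=True)

    pred = 0.0
    for stratum, weight in rho.items():
        cell = sub[sub["stratum"] == stratum]["chose_low_mean"].astype(bool)
        if len(cell) == 0:
            raise UndefinedStatisticError(f"stratum {stratum} occupied but empty")
        p = float(cell.mean())
        n = len(cell)
        correction = n / (n - 1) if (bias_corrected and n > 1) else 1.0
        # the true 2p(1-p) never exceeds 1/2, so the debiased stratum value
        # is clipped there
        pred += float(weight) * min(2.0 * p * (1.0 - p) * correction, 0.5)
    return pred


def subject_stats(rows: pd.DataFrame, n_bins: int = 4) -> pd.DataFrame:
    """Per subject x horizon table of all model-free statistics.

    Statistics whose preconditions fail for a subject are reported as NaN.
    """
    records = []
    for (subject, horizon), sub in rows.groupby(["subject_id", "horizon"]):
        rec = {"subject_id": subject, "horizon": horizon}

        def attempt(name, fn, *args, **kw):
            try:
                rec[name] = fn(sub, horizon, *args, **kw)
            except UndefinedStatisticError:
                rec[name] = np.nan

        attempt("p_low_mean", lambda s, h: p_low_mean(s, h))
        attempt("p_high_info", lambda s, h: p_high_info(s, h))
        for info in ("13", "22"):
            attempt(f"p_inconsistent_{info}", p_inconsistent, info)
            attempt(
                f"predicted_inconsistent_random_{info}",
                pure_random_prediction,
                info,
                n_bins,
            )
            rec[f"predicted_inconsistent_deterministic_{info}"] = (
                PURE_DETERMINISTIC_PREDICTION
            )
            try:
                rec[f"n_pairs_{info}"] = len(
                    _complete_pairs(_eligible(sub, horizon, info))
                ) // 2
            except UndefinedStatisticError:  # pragma: no cover
                rec[f"n_pairs_{info}"] = 0
            rec[f"n_games_{info}"] = len(_eligible(sub, horizon, info))
        records.append(rec)
    return pd.DataFrame(records)


@dataclass(frozen=True)
class HorizonContrast:
    """Two-sided paired t-test of a statistic between horizons 6 and 1."""

    t: float
    df: int
    p: float
    mean_diff: float
    degenerate: bool = False


def horizon_contrast(stats_table: pd.DataFrame, column: str) -> HorizonContrast:
    """Paired t-test of horizon-6 minus horizon-1 values of ``column``.

    Subjects missing the statistic at either horizon are dropped pairwise.
    A zero-variance nonzero difference is flagged degenerate (infinite t).
    """
    wide = stats_table.pivot(index="subject_id", columns="horizon", values=column)
    if 1 not in wide.columns or 6 not in wide.columns:
        raise UndefinedStatisticError("need both horizons for a contrast")
    wide = wide.dropna()
    if len(wide) < 2:
        raise UndefinedStatisticError("need at least 2 subjects for a paired t-test")
    diff = (wide[6] - wide[1]).to_numpy(dtype=float)
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):
            return HorizonContrast(0.0, len(diff) - 1, 1.0, 0.0)
        return HorizonContrast(
            float(np.inf) * np.sign(diff.mean()), len(diff) - 1, 0.0,
            float(diff.mean()), degenerate=True,
        )
    res = sps.ttest_rel(wide[6], wide[1])
    return HorizonContrast(
        float(res.statistic), len(wide) - 1, float(res.pvalue), float(diff.mean())
    )


def exclude_subjects(trials: pd.DataFrame, alpha: float = 0.001) -> pd.DataFrame:
    """Performance-based exclusion on horizon-6 last-choice accuracy.

    A subject is kept when the fraction of 10th-trial choices landing on the
    bandit with the higher generative mean beats chance in a one-sided exact
    binomial test at ``p < alpha``.  Generative means are taken from the
    ``mean_left`` / ``mean_right`` columns when present, otherwise estimated
    from all observed rewards of the game.

    Returns a DataFrame (subject_id, n_last, n_correct, accuracy, p_value,
    kept, reason).
    """
    validate_trials(trials)
    has_means = {"mean_left", "mean_right"} <= set(trials.columns)
    records = []
    for subject, sub in trials.groupby("subject_id"):
        last = sub[(sub["horizon"] == 6) & (sub["trial_index"] == 10)]
        if len(last) == 0:
            records.append(
                dict(subject_id=subject, n_last=0, n_correct=0,
                     accuracy=np.nan, p_value=np.nan, kept=False,
                     reason="no horizon-6 games")
            )
            continue
        if has_means:
            better = np.where(
                last["mean_right"].to_numpy() > last["mean_left"].to_numpy(),
                "right", "left",
            )
        else:
            per_side = sub.pivot_table(
                index="game_id", columns="side", values="reward", aggfunc="mean"
            )
            better = np.where(
                per_side.loc[last["game_id"], "right"].to_numpy()
                > per_side.loc[last["game_id"], "left"].to_numpy(),
                "right", "left",
            )
        correct = int((last["side"].to_numpy() == better).sum())
        n = len(last)
        pval = sps.binomtest(correct, n, 0.5, alternative="greater").pvalue
        kept = pval < alpha
        records.append(
            dict(subject_id=subject, n_last=n, n_correct=correct,
                 accuracy=correct / n, p_value=float(pval), kept=bool(kept),
                 reason="" if kept else "accuracy not above chance")
        )
    return pd.DataFrame(records)
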