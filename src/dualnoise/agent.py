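"""Generative two-noise logistic chooser for the repeated-games Horizon Task.

The decision variable for the first free choice of a game is

    dQ = dR + A*dI + b + n_det + n_ran

where ``dR`` is the forced-trial mean reward difference (right minus left),
``dI`` the information difference (+1/-1/0), ``A`` the information bonus and
``b`` a rightward spatial bias.  ``n_det`` is *deterministic noise*: a value
frozen to the stimulus, hence identical across the two members of a repeated
game pair.  ``n_ran`` is *random noise*, drawn fresh on every play.  Both are
zero-mean logistic variates; ``sigma_det`` / ``sigma_ran`` are their scale
parameters (SD = scale * pi / sqrt(3); construct params with
``SubjectParams.from_sd`` if you think in standard deviations).  The agent
chooses right when dQ > 0, which marginalizing over n_ran gives the logistic
choice rule ``P(right) = expit((dR + A*dI + b + n_det) / sigma_ran)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.special import expit

from ._exceptions import ConfigurationError
from .task import GameSpec, TaskConfig, _draw_rewards, play_forced_trials

__all__ = [
    "SubjectParams",
    "LOGISTIC_SD_PER_SCALE",
    "delta_Q",
    "choice_prob_right",
    "sample_logistic",
    "play_session",
    "simulate_first_choices",
    "reward_scaling_transform",
    "marginal_choice_prob_right",
    "pair_agreement_prob",
]

#: SD of a unit-scale logistic distribution.
LOGISTIC_SD_PER_SCALE = math.pi / math.sqrt(3.0)


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject, per-horizon parameters of the two-noise chooser.

    ``sigma_det`` and ``sigma_ran`` are logistic *scale* parameters.
    """

    A: float = 0.0
    b: float = 0.0
    sigma_det: float = 0.0
    sigma_ran: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_det < 0 or self.sigma_ran < 0:
            raise ConfigurationError("noise scales must be non-negative")

    @classmethod
    def from_sd(cls, A=0.0, b=0.0, sd_det=0.0, sd_ran=0.0) -> "SubjectParams":
        """Build from logistic standard deviations instead of scales."""
        return cls(
            A=A,
            b=b,
            sigma_det=sd_det / LOGISTIC_SD_PER_SCALE,
            sigma_ran=sd_ran / LOGISTIC_SD_PER_SCALE,
        )


def delta_Q(params: SubjectParams, delta_R, delta_I, n_det, n_ran):
    """Decision variable dR + A*dI + b + n_det + n_ran (vectorized)."""
    return (
        np.asarray(delta_R, dtype=float)
        + params.A * np.asarray(delta_I, dtype=float)
        + params.b
        + np.asarray(n_det, dtype=float)
        + np.asarray(n_ran, dtype=float)
    )


def choice_prob_right(params: SubjectParams, delta_R, delta_I, n_det):
    """P(choose right) given the frozen noise, marginal over random noise.

    With ``sigma_ran == 0`` the rule degenerates to a hard threshold and the
    probability is 0, 1/2 or 1 by the sign of the drive.
    """
    drive = delta_Q(params, delta_R, delta_I, n_det, 0.0)
    if params.sigma_ran == 0:
        return np.where(drive > 0, 1.0, np.where(drive < 0, 0.0, 0.5))
    return expit(drive / params.sigma_ran)


def sample_logistic(scale: float, size, rng: np.random.Generator):
    """Zero-mean logistic draws with the given scale (0 gives exact zeros)."""
    if scale == 0:
        return np.zeros(() if size is None else size)
    return rng.logistic(0.0, scale, size=size)


def reward_scaling_transform(params: SubjectParams, beta: float) -> SubjectParams:
    """Parameters equivalent to scaling the reward signal by ``beta``.

    Because choice depends only on the sign of dQ, multiplying dR by beta is
    behaviorally identical to dividing A, b and both noise scales by beta.
    """
    if beta <= 0:
        raise ConfigurationError("beta must be positive")
    return SubjectParams(
        A=params.A / beta,
        b=params.b / beta,
        sigma_det=params.sigma_det / beta,
        sigma_ran=params.sigma_ran / beta,
    )


def _choose(p_right: float, rng: np.random.Generator) -> str:
    return "right" if rng.random() < p_right else "left"


def play_session(
    params_by_horizon: dict[int, SubjectParams],
    games: list[GameSpec],
    rng: np.random.Generator,
    config: TaskConfig | None = None,
    subject_id: str = "s0",
) -> pd.DataFrame:
    """Play a session and return its trial table.

    Forced trials reproduce each game's schedule verbatim.  The first free
    choice follows the two-noise rule with one frozen-noise draw per repeated
    pair (drawn lazily at the pair's first appearance, so presentation order
    cannot alter pair-level draws) and fresh random noise each game.  Later
    free choices of horizon-6 games — which no analysis here consumes — use a
    simple greedy-on-sample-means policy with the same logistic random noise
    and carry ``analysis = 0``.
    """
    config = config or TaskConfig()
    for g in games:
        if g.horizon not in params_by_horizon:
            raise ConfigurationError(f"no parameters supplied for horizon {g.horizon}")

    frozen: dict[str, float] = {}
    rows: list[dict] = []
    for game in games:
        params = params_by_horizon[game.horizon]
        key = game.pair_id if game.pair_id is not None else f"g{game.game_id}"
        if key not in frozen:
            frozen[key] = float(sample_logistic(params.sigma_det, None, rng))
        n_det = frozen[key]

        game_rows = play_forced_trials(game, subject_id)
        rewards = {"left": [], "right": []}
        for r in game_rows:
            rewards[r["side"]].append(r["reward"])

        mean = lambda s: float(np.mean(rewards[s]))
        delta_R = mean("right") - mean("left")
        if game.info_condition == "22":
            delta_I = 0
        else:
            delta_I = 1 if len(rewards["right"]) == 1 else -1

        p_right = float(choice_prob_right(params, delta_R, delta_I, n_det))
        side = _choose(p_right, rng)
        reward = int(_draw_rewards(game.mean_of(side), 1, config, rng)[0])
        rewards[side].append(reward)
        game_rows.append(
            {
                **{k: game_rows[0][k] for k in (
                    "subject_id", "game_id", "pair_id", "repeat_index",
                    "horizon", "info_condition", "mean_left", "mean_right",
                )},
                "trial_index": 5,
                "is_forced": 0,
                "side": side,
                "reward": reward,
                "analysis": 1,
            }
        )

        for t in range(6, 4 + game.horizon + 1):
            drive = mean("right") - mean("left") + params.b
            if params.sigma_ran == 0:
                p = 1.0 if drive > 0 else (0.0 if drive < 0 else 0.5)
            else:
                p = float(expit(drive / params.sigma_ran))
            side = _choose(p, rng)
            reward = int(_draw_rewards(game.mean_of(side), 1, config, rng)[0])
            rewards[side].append(reward)
            game_rows.append(
                {
                    **{k: game_rows[0][k] for k in (
                        "subject_id", "game_id", "pair_id", "repeat_index",
                        "horizon", "info_condition", "mean_left", "mean_right",
                    )},
                    "trial_index": t,
                    "is_forced": 0,
                    "side": side,
                    "reward": reward,
                    "analysis": 0,
                }
            )
        rows.extend(game_rows)
    return pd.DataFrame(rows)


def simulate_first_choices(
    params_by_horizon: dict[int, SubjectParams],
    games: list[GameSpec],
    rng: np.random.Generator,
    subject_id: str = "s0",
) -> pd.DataFrame:
    """Simulate only the first free choice of each game.

    Returns the same first-free-choice rows that
    :func:`dualnoise.task.first_free_choices` would derive from a full trial
    table, an order of magnitude faster — used by posterior predictive
    replays, where only these rows feed the statistics.  Frozen-noise draws
    are shared within pairs exactly as in :func:`play_session`.
    """
    for g in games:
        if g.horizon not in params_by_horizon:
            raise ConfigurationError(f"no parameters supplied for horizon {g.horizon}")
    frozen: dict[str, float] = {}
    recs = []
    for game in games:
        params = params_by_horizon[game.horizon]
        key = game.pair_id if game.pair_id is not None else f"g{game.game_id}"
        if key not in frozen:
            frozen[key] = float(sample_logistic(params.sigma_det, None, rng))
        n_det = frozen[key]

        rewards = {"left": [], "right": []}
        for s, r in zip(game.forced_sides, game.forced_rewards):
            rewards[s].append(r)
        mean_l = float(np.mean(rewards["left"]))
        mean_r = float(np.mean(rewards["right"]))
        delta_R = mean_r - mean_l
        if game.info_condition == "22":
            delta_I = 0
        else:
            delta_I = 1 if len(rewards["right"]) == 1 else -1
        p_right = float(choice_prob_right(params, delta_R, delta_I, n_det))
        chose_right = bool(rng.random() < p_right)
        chosen_mean = mean_r if chose_right else mean_l
        other_mean = mean_l if chose_right else mean_r
        tie = np.isclose(mean_l, mean_r)
        chosen_count = len(rewards["right"] if chose_right else rewards["left"])
        recs.append(
            dict(
                subject_id=subject_id,
                game_id=game.game_id,
                pair_id="" if game.pair_id is None else game.pair_id,
                repeat_index=0 if game.repeat_index is None else game.repeat_index,
                horizon=game.horizon,
                info_condition=game.info_condition,
                delta_R=delta_R,
                delta_I=delta_I,
                var_left=float(np.var(rewards["left"])),
                var_right=float(np.var(rewards["right"])),
                chose_right=chose_right,
                chose_low_mean=None if tie else bool(chosen_mean < other_mean),
                chose_high_info=(
                    bool(chosen_count == 1) if game.info_condition == "13" else None
                ),
            )
        )
    out = pd.DataFrame(recs)
    out["chose_low_mean"] = out["chose_low_mean"].astype("boolean")
    out["chose_high_info"] = out["chose_high_info"].astype("boolean")
    return out


def marginal_choice_prob_right(
    params: SubjectParams, delta_R: float, delta_I: float
) -> float:
    """P(choose right) marginalized over the frozen noise by quadrature."""
    if params.sigma_det == 0:
        return float(choice_prob_right(params, delta_R, delta_I, 0.0))
    s = params.sigma_det

    def integrand(x):
        dens = np.exp(-abs(x) / s) / (s * (1 + np.exp(-abs(x) / s)) ** 2)
        return dens * choice_prob_right(params, delta_R, delta_I, x)

    val, _ = quad(integrand, -np.inf, np.inf, limit=200)
    return float(val)


def pair_agreement_prob(params: SubjectParams, delta_R: float, delta_I: float) -> float:
    """P(the two first free choices of a repeated pair agree).

    Conditional on the shared frozen noise the two choices are independent
    with the same probability p, so agreement is E[p^2 + (1-p)^2] over the
    frozen-noise distribution.
    """
    if params.sigma_det == 0:
        p = float(choice_prob_right(params, delta_R, delta_I, 0.0))
        return p * p + (1 - p) * (1 - p)
    s = params.sigma_det

    def integrand(x):
        dens = np.exp(-abs(x) / s) / (s * (1 + np.exp(-abs(x) / s)) ** 2)
        p = choice_prob_right(params, delta_R, delta_I, x)
        return dens * (p * p + (1 - p) * (1 - p))

    val, _ = quad(integrand, -np.inf, np.inf, limit=200)
    return float(val)
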