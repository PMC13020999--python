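"""Synthetic repeated-games Horizon Task sessions.

The Horizon Task is a two-armed bandit game: payoffs are Gaussian with a fixed
standard deviation (8 points by default) and per-game means, one of which is
anchored at 40 or 60 while the other differs by 4, 8, 12 or 20 points.  Each
game opens with four forced plays that set up an information condition —
``"13"`` (one side played once, the other three times) or ``"22"`` (both sides
twice) — followed by 1 or 6 free choices (the horizon).  The repeated-games
variant duplicates most games: the two members of a pair share the exact same
forced-trial sides and outcomes and are separated in presentation order so the
repetition goes unnoticed.  Choice consistency across those pairs is what lets
downstream analyses split decision noise into a stimulus-frozen and a per-play
random component.

This module generates such sessions (:func:`generate_game`,
:func:`generate_session`), defines the long-format trial table, and reduces a
trial table to the per-game first-free-choice rows (:func:`first_free_choices`)
that every analysis in the package consumes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError, DataError, GenerationError

__all__ = [
    "TaskConfig",
    "GameSpec",
    "TRIAL_COLUMNS",
    "generate_game",
    "generate_session",
    "play_forced_trials",
    "first_free_choices",
    "validate_trials",
]

#: Required columns of the long-format trial table, in file order.
TRIAL_COLUMNS = [
    "subject_id",
    "game_id",
    "pair_id",
    "repeat_index",
    "horizon",
    "info_condition",
    "trial_index",
    "is_forced",
    "side",
    "reward",
]

#: Optional columns a trial table may carry in addition to TRIAL_COLUMNS.
OPTIONAL_TRIAL_COLUMNS = ["analysis", "mean_left", "mean_right"]

_SIDES = ("left", "right")


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the synthetic task.

    Defaults reproduce the study conditions: payoff SD 8 points, anchors
    {40, 60}, mean differences {4, 8, 12, 20}, rewards clipped to [1, 100],
    156 games of which 65 pairs are duplicated, and at least 10 intervening
    games between the two members of a pair.
    """

    reward_sd: float = 8.0
    mean_anchor_set: tuple[float, ...] = (40.0, 60.0)
    mean_diff_set: tuple[float, ...] = (4.0, 8.0, 12.0, 20.0)
    reward_min: int = 1
    reward_max: int = 100
    n_games: int = 156
    repeat_fraction: float = 130 / 156
    min_pair_separation: int = 10
    horizon_set: tuple[int, ...] = (1, 6)
    info_condition_set: tuple[str, ...] = ("13", "22")
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.reward_sd <= 0:
            raise ConfigurationError("reward_sd must be positive")
        if self.n_games < 2:
            raise ConfigurationError("n_games must be at least 2")
        if self.min_pair_separation < 1:
            raise ConfigurationError("min_pair_separation must be >= 1")
        if not 0.0 <= self.repeat_fraction <= 1.0:
            raise ConfigurationError("repeat_fraction must lie in [0, 1]")
        if self.reward_min >= self.reward_max:
            raise ConfigurationError("reward_min must be below reward_max")
        bad_h = set(self.horizon_set) - {1, 6}
        if bad_h:
            raise ConfigurationError(f"unsupported horizons: {sorted(bad_h)}")
        bad_i = set(self.info_condition_set) - {"13", "22"}
        if bad_i:
            raise ConfigurationError(f"unsupported info conditions: {sorted(bad_i)}")

    @property
    def n_pairs(self) -> int:
        """Number of duplicated game pairs implied by ``repeat_fraction``."""
        return int(round(self.n_games * self.repeat_fraction / 2))

    @property
    def n_unpaired(self) -> int:
        return self.n_games - 2 * self.n_pairs


@dataclass(frozen=True)
class GameSpec:
    """One bandit game: stimulus schedule and generative means.

    Two GameSpecs sharing a ``pair_id`` are stimulus-identical: same horizon,
    information condition, means, forced sides and forced rewards.
    """

    game_id: int
    pair_id: str | None
    repeat_index: int | None
    horizon: int
    info_condition: str
    mean_left: float
    mean_right: float
    forced_sides: tuple[str, str, str, str]
    forced_rewards: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        counts = {s: self.forced_sides.count(s) for s in _SIDES}
        expected = {"13": {1, 3}, "22": {2}}[self.info_condition]
        if set(counts.values()) != expected:
            raise ConfigurationError(
                f"forced_sides {self.forced_sides} inconsistent with "
                f"info condition {self.info_condition}"
            )

    def stimulus_fields(self) -> tuple:
        """The fields that must match exactly across a repeated pair."""
        return (
            self.horizon,
            self.info_condition,
            self.mean_left,
            self.mean_right,
            self.forced_sides,
            self.forced_rewards,
        )

    @property
    def n_trials(self) -> int:
        return 4 + self.horizon

    def mean_of(self, side: str) -> float:
        return self.mean_left if side == "left" else self.mean_right

    @property
    def higher_mean_side(self) -> str:
        return "left" if self.mean_left > self.mean_right else "right"


def _draw_rewards(mean: float, n: int, config: TaskConfig, rng: np.random.Generator):
    """Gaussian payoffs rounded to integers and clamped to the payout bounds."""
    raw = rng.normal(mean, config.reward_sd, size=n)
    return np.clip(np.rint(raw), config.reward_min, config.reward_max).astype(int)


def _forced_sides(info_condition: str, rng: np.random.Generator):
    if info_condition == "22":
        sides = ["left", "left", "right", "right"]
        rng.shuffle(sides)
        return tuple(sides)
    once = _SIDES[rng.integers(2)]
    thrice = "right" if once == "left" else "left"
    sides = [thrice] * 4
    sides[rng.integers(4)] = once
    return tuple(sides)


def _draw_means(config: TaskConfig, mean_diff: float, rng: np.random.Generator):
    anchor = float(config.mean_anchor_set[rng.integers(len(config.mean_anchor_set))])
    sign = 1.0 if rng.integers(2) == 0 else -1.0
    other = anchor + sign * mean_diff
    if other in config.mean_anchor_set and mean_diff > 0:
        other = anchor - sign * mean_diff  # keep exactly one mean on an anchor
    if rng.integers(2) == 0:
        return anchor, other
    return other, anchor


def _make_game(
    config: TaskConfig,
    horizon: int,
    info_condition: str,
    mean_diff: float,
    rng: np.random.Generator,
    game_id: int = 0,
) -> GameSpec:
    mean_left, mean_right = _draw_means(config, mean_diff, rng)
    sides = _forced_sides(info_condition, rng)
    rewards = tuple(
        int(_draw_rewards(mean_left if s == "left" else mean_right, 1, config, rng)[0])
        for s in sides
    )
    return GameSpec(
        game_id=game_id,
        pair_id=None,
        repeat_index=None,
        horizon=horizon,
        info_condition=info_condition,
        mean_left=mean_left,
        mean_right=mean_right,
        forced_sides=sides,
        forced_rewards=rewards,
    )


def generate_game(
    config: TaskConfig,
    horizon: int,
    info_condition: str,
    rng: np.random.Generator,
) -> GameSpec:
    """Draw a single (unpaired) game for the given condition cell.

    The anchored mean lands on a uniformly chosen side, the mean difference is
    drawn uniformly from ``config.mean_diff_set``, forced sides are a uniform
    ordering consistent with the information condition, and forced rewards are
    integer-rounded Gaussian draws clipped to the payout bounds.
    """
    if horizon not in config.horizon_set:
        raise ConfigurationError(f"horizon {horizon} not in {config.horizon_set}")
    if info_condition not in config.info_condition_set:
        raise ConfigurationError(
            f"info condition {info_condition!r} not in {config.info_condition_set}"
        )
    mean_diff = float(config.mean_diff_set[rng.integers(len(config.mean_diff_set))])
    return _make_game(config, horizon, info_condition, mean_diff, rng)


def _allocate_cells(config: TaskConfig, rng: np.random.Generator):
    """Counterbalance condition cells over paired and unpaired base games.

    Pairs are dealt round-robin over the horizon x info x mean-diff cells;
    unpaired games then fill whichever horizon x info cell currently holds the
    fewest games, so per-cell game counts differ by at most one whenever the
    arithmetic allows it.
    """
    hi_cells = list(itertools.product(config.horizon_set, config.info_condition_set))
    diffs = list(config.mean_diff_set)
    full_cells = [(h, i, d) for (h, i) in hi_cells for d in diffs]
    rng.shuffle(full_cells)

    pair_cells = [full_cells[k % len(full_cells)] for k in range(config.n_pairs)]
    games_per_hi = {hi: 0 for hi in hi_cells}
    for h, i, _ in pair_cells:
        games_per_hi[(h, i)] += 2

    diff_cycle = {hi: itertools.cycle(diffs) for hi in hi_cells}
    unpaired_cells = []
    for _ in range(config.n_unpaired):
        order = sorted(games_per_hi, key=lambda hi: (games_per_hi[hi], rng.random()))
        hi = order[0]
        games_per_hi[hi] += 1
        unpaired_cells.append((hi[0], hi[1], next(diff_cycle[hi])))
    return pair_cells, unpaired_cells


def _schedule_positions(
    n_games: int,
    n_pairs: int,
    min_separation: int,
    rng: np.random.Generator,
    max_passes: int = 2000,
):
    """Assign presentation slots so pair members have >= min_separation
    intervening games, by random placement plus local swap repair."""
    if min_separation + 2 > n_games:
        raise GenerationError(
            f"cannot separate a pair by {min_separation} games in a "
            f"{n_games}-game session"
        )
    # instance k < 2*n_pairs belongs to pair k // 2; the rest are unpaired
    n_inst = n_games
    order = rng.permutation(n_inst)
    pos = np.empty(n_inst, dtype=int)
    pos[order] = np.arange(n_inst)

    def violations():
        bad = []
        for p in range(n_pairs):
            a, b = pos[2 * p], pos[2 * p + 1]
            if abs(a - b) - 1 < min_separation:
                bad.append(p)
        return bad

    for _ in range(max_passes):
        bad = violations()
        if not bad:
            return pos
        for p in bad:
            # move the second member to a random slot (swap occupants)
            j = 2 * p + 1
            target = int(rng.integers(n_inst))
            other = int(np.where(pos == target)[0][0])
            pos[other], pos[j] = pos[j], pos[other]
    raise GenerationError(
        f"could not schedule {n_pairs} pairs with separation "
        f">= {min_separation} in {n_games} games"
    )


def generate_session(config: TaskConfig, rng: np.random.Generator) -> list[GameSpec]:
    """Generate one subject's session: a presentation-ordered list of games.

    Duplicated games share all stimulus fields; the two members of each pair
    are separated by at least ``config.min_pair_separation`` intervening
    games; conditions are counterbalanced across cells as far as divisibility
    allows; order is otherwise random.
    """
    pair_cells, unpaired_cells = _allocate_cells(config, rng)
    base_games = [
        _make_game(config, h, i, d, rng) for (h, i, d) in pair_cells
    ] + [_make_game(config, h, i, d, rng) for (h, i, d) in unpaired_cells]

    pos = _schedule_positions(
        config.n_games, config.n_pairs, config.min_pair_separation, rng
    )

    session: list[GameSpec | None] = [None] * config.n_games
    for inst in range(config.n_games):
        if inst < 2 * config.n_pairs:
            base_idx = inst // 2
            pair_id = f"p{base_idx}"
        else:
            base_idx = config.n_pairs + (inst - 2 * config.n_pairs)
            pair_id = None
        slot = int(pos[inst])
        session[slot] = replace(
            base_games[base_idx], game_id=slot, pair_id=pair_id, repeat_index=None
        )
    out = [g for g in session if g is not None]
    assert len(out) == config.n_games
    # repeat_index must follow presentation order, not instance order
    seen: dict[str, int] = {}
    fixed = []
    for g in out:
        if g.pair_id is None:
            fixed.append(g)
            continue
        seen[g.pair_id] = seen.get(g.pair_id, 0) + 1
        fixed.append(replace(g, repeat_index=seen[g.pair_id]))
    return fixed


def play_forced_trials(game: GameSpec, subject_id: str) -> list[dict]:
    """Rows for the four instructed trials of one game."""
    rows = []
    for t in range(4):
        rows.append(
            {
                "subject_id": subject_id,
                "game_id": game.game_id,
                "pair_id": "" if game.pair_id is None else game.pair_id,
                "repeat_index": 0 if game.repeat_index is None else game.repeat_index,
                "horizon": game.horizon,
                "info_condition": game.info_condition,
                "trial_index": t + 1,
                "is_forced": 1,
                "side": game.forced_sides[t],
                "reward": game.forced_rewards[t],
                "analysis": 1,
                "mean_left": game.mean_left,
                "mean_right": game.mean_right,
            }
        )
    return rows


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Check the trial-table invariants, returning the table unchanged.

    Raises :class:`DataError` naming the first offending game or row.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise DataError(f"trial table missing columns: {missing}")
    bad_h = set(trials["horizon"].unique()) - {1, 6}
    if bad_h:
        row = trials.index[~trials["horizon"].isin([1, 6])][0]
        raise DataError(f"row {row}: horizon must be 1 or 6, got {bad_h}")
    bad_i = set(trials["info_condition"].astype(str).unique()) - {"13", "22"}
    if bad_i:
        raise DataError(f"info_condition must be '13' or '22', got {bad_i}")
    bad_side = set(trials["side"].unique()) - set(_SIDES)
    if bad_side:
        raise DataError(f"side must be left/right, got {bad_side}")
    if not np.isfinite(trials["reward"].to_numpy(dtype=float)).all():
        raise DataError("non-numeric reward value")

    grouped = trials.groupby(["subject_id", "game_id"], sort=False)
    sizes = grouped.size()
    horizons = grouped["horizon"].first()
    expected = horizons.map({1: 5, 6: 10})
    wrong = sizes[sizes != expected]
    if len(wrong):
        raise DataError(
            f"game {wrong.index[0]} has {wrong.iloc[0]} rows, "
            f"expected {expected.loc[wrong.index[0]]}"
        )
    forced = trials[trials["trial_index"] <= 4]
    if not (forced["is_forced"] == 1).all():
        row = forced.index[forced["is_forced"] != 1][0]
        raise DataError(f"row {row}: trials 1-4 must be forced")
    free = trials[trials["trial_index"] > 4]
    if not (free["is_forced"] == 0).all():
        row = free.index[free["is_forced"] != 0][0]
        raise DataError(f"row {row}: trials 5+ must not be forced")
    n_forced_sides = forced.groupby(["subject_id", "game_id"], sort=False)[
        "side"
    ].apply(lambda s: (s == "right").sum())
    info = forced.groupby(["subject_id", "game_id"], sort=False)[
        "info_condition"
    ].first().astype(str)
    want = info.map({"22": {2}, "13": {1, 3}})
    mismatch = [
        k for k, nr in n_forced_sides.items() if nr not in want.loc[k]
    ]
    if mismatch:
        raise DataError(f"game {mismatch[0]}: forced sides violate info condition")
    return trials


def first_free_choices(trials: pd.DataFrame) -> pd.DataFrame:
    """Reduce a trial table to one row per game: the first free choice.

    Returns a DataFrame with columns ``subject_id, game_id, pair_id,
    repeat_index, horizon, info_condition, delta_R, delta_I, var_left,
    var_right, chose_right, chose_low_mean, chose_high_info``, where

    * ``delta_R`` is the forced-trial mean reward difference (right - left),
    * ``delta_I`` is +1 when the right option was played once in a "13" game,
      -1 when the left was, and 0 in "22" games,
    * ``chose_low_mean`` is pandas NA when the forced means tie,
    * ``chose_high_info`` is defined only for "13" games,
    * ``var_left/var_right`` are forced-reward population variances (used by
      the variance-based information-difference model variant).
    """
    validate_trials(trials)
    keys = ["subject_id", "game_id"]
    forced = trials[trials["is_forced"] == 1]
    free5 = trials[trials["trial_index"] == 5]
    n_games = trials.groupby(keys, sort=False).ngroups
    if len(free5) != n_games:
        have = set(map(tuple, free5[keys].itertuples(index=False)))
        allg = set(map(tuple, trials[keys].drop_duplicates().itertuples(index=False)))
        raise DataError(f"games missing trial 5: {sorted(allg - have)[:3]}")

    def _per_side(stat):
        wide = forced.pivot_table(
            index=keys, columns="side", values="reward", aggfunc=stat
        )
        for s in _SIDES:
            if s not in wide:
                wide[s] = np.nan
        return wide

    means = _per_side("mean")
    counts = _per_side("count")
    variances = _per_side(lambda x: np.var(np.asarray(x, dtype=float)))

    out = free5.set_index(keys)[
        ["pair_id", "repeat_index", "horizon", "info_condition", "side"]
    ].copy()
    out["info_condition"] = out["info_condition"].astype(str)
    out["delta_R"] = means["right"] - means["left"]
    right_once = counts["right"] == 1
    out["delta_I"] = np.where(
        out["info_condition"] == "22", 0, np.where(right_once, 1, -1)
    )
    out["var_left"] = variances["left"].fillna(0.0)
    out["var_right"] = variances["right"].fillna(0.0)
    out["chose_right"] = out["side"] == "right"

    chosen_mean = np.where(out["chose_right"], means["right"], means["left"])
    other_mean = np.where(out["chose_right"], means["left"], means["right"])
    tie = np.isclose(means["right"], means["left"])
    out["chose_low_mean"] = pd.array(
        np.where(tie, None, chosen_mean < other_mean), dtype="boolean"
    )
    out.loc[tie, "chose_low_mean"] = pd.NA

    chosen_count = np.where(out["chose_right"], counts["right"], counts["left"])
    is13 = out["info_condition"] == "13"
    out["chose_high_info"] = pd.array(
        np.where(is13, chosen_count == 1, None), dtype="boolean"
    )
    out.loc[~is13, "chose_high_info"] = pd.NA
    return out.drop(columns="side").reset_index()
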