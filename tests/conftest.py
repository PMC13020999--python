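import numpy as np
import pandas as pd
import pytest

from dualnoise.agent import SubjectParams, play_session
from dualnoise.task import TaskConfig, generate_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_config():
    return TaskConfig()


@pytest.fixture(scope="session")
def session_games(default_config):
    return generate_session(default_config, np.random.default_rng(7))


@pytest.fixture(scope="session")
def small_trials(default_config, session_games):
    """One simulated subject's full trial table (moderate two-noise agent)."""
    params = {
        1: SubjectParams(A=1.0, b=0.3, sigma_det=1.5, sigma_ran=3.0),
        6: SubjectParams(A=4.0, b=0.3, sigma_det=3.0, sigma_ran=7.0),
    }
    return play_session(
        params, session_games, np.random.default_rng(11), default_config, "s0"
    )


def make_game_rows(
    subject="s0",
    game_id=0,
    horizon=1,
    info="22",
    forced_sides=("left", "left", "right", "right"),
    forced_rewards=(50, 50, 40, 40),
    free_sides=("right",),
    pair_id="",
    repeat_index=0,
    rewards_free=None,
):
    """Hand-build the trial rows of one game."""
    rows = []
    for t, (s, r) in enumerate(zip(forced_sides, forced_rewards), start=1):
        rows.append(
            dict(subject_id=subject, game_id=game_id, pair_id=pair_id,
                 repeat_index=repeat_index, horizon=horizon, info_condition=info,
                 trial_index=t, is_forced=1, side=s, reward=r)
        )
    rewards_free = rewards_free or [50] * len(free_sides)
    for t, (s, r) in enumerate(zip(free_sides, rewards_free), start=5):
        rows.append(
            dict(subject_id=subject, game_id=game_id, pair_id=pair_id,
                 repeat_index=repeat_index, horizon=horizon, info_condition=info,
                 trial_index=t, is_forced=0, side=s, reward=r)
        )
    return rows


@pytest.fixture
def game_rows_factory():
    return make_game_rows


def trials_frame(*game_row_lists):
    return pd.DataFrame([r for rows in game_row_lists for r in rows])


@pytest.fixture
def trials_builder():
    return trials_frame
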