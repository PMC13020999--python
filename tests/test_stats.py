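"""Model-free statistics: counting, pure-noise bounds, contrasts, exclusion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from dualnoise import (
    UndefinedStatisticError,
    exclude_subjects,
    horizon_contrast,
    p_high_info,
    p_inconsistent,
    p_low_mean,
    pure_random_prediction,
    subject_stats,
)
from tests.conftest import make_game_rows, trials_frame


def rows_frame(records):
    df = pd.DataFrame(records)
    for col, default in (
        ("pair_id", ""),
        ("delta_R", 5.0),
        ("delta_I", 0),
        ("chose_right", True),
        ("chose_high_info", None),
    ):
        if col not in df:
            df[col] = default
    if "game_id" not in df:
        df["game_id"] = np.arange(len(df))
    if "subject_id" not in df:
        df["subject_id"] = "s0"
    df["chose_low_mean"] = pd.array(df.get("chose_low_mean"), dtype="boolean")
    df["chose_high_info"] = pd.array(df["chose_high_info"], dtype="boolean")
    return df


class TestCountingStats:
    def test_p_low_mean_counts(self):
        rows = rows_frame(
            [dict(horizon=1, info_condition="22", chose_low_mean=i < 3)
             for i in range(10)]
        )
        assert p_low_mean(rows, 1) == pytest.approx(0.3)
        none_low = rows_frame(
            [dict(horizon=1, info_condition="22", chose_low_mean=False)
             for _ in range(5)]
        )
        assert p_low_mean(none_low, 1) == 0.0

    def test_p_low_mean_undefined_on_all_ties(self):
        rows = rows_frame(
            [dict(horizon=1, info_condition="22", chose_low_mean=None)
             for _ in range(4)]
        )
        with pytest.raises(UndefinedStatisticError):
            p_low_mean(rows, 1)

    def test_p_high_info_counts(self):
        rows = rows_frame(
            [dict(horizon=6, info_condition="13", chose_low_mean=False,
                  chose_high_info=i < 6) for i in range(10)]
        )
        assert p_high_info(rows, 6) == pytest.approx(0.6)
        with pytest.raises(UndefinedStatisticError):
            p_high_info(rows, 1)

    def test_p_inconsistent_counts(self):
        recs = []
        for k in range(16):
            differ = k < 4
            for member, right in ((1, True), (2, not differ)):
                recs.append(
                    dict(horizon=1, info_condition="22", pair_id=f"p{k}",
                         chose_right=right, chose_low_mean=right,
                         game_id=f"{k}_{member}")
                )
        rows = rows_frame(recs)
        assert p_inconsistent(rows, 1, "22") == pytest.approx(4 / 16)

    def test_p_inconsistent_fair_coin_limit(self, rng):
        n = 3000
        recs = []
        for k in range(n):
            for member in (1, 2):
                recs.append(
                    dict(horizon=1, info_condition="22", pair_id=f"p{k}",
                         chose_right=bool(rng.integers(2)),
                         chose_low_mean=True, game_id=f"{k}_{member}")
                )
        rows = rows_frame(recs)
        se = 0.5 / np.sqrt(n)
        assert abs(p_inconsistent(rows, 1, "22") - 0.5) < 4 * se

    def test_p_inconsistent_requires_complete_pairs(self):
        rows = rows_frame(
            [dict(horizon=1, info_condition="22", pair_id="p0",
                  chose_low_mean=True)]
        )
        with pytest.raises(UndefinedStatisticError):
            p_inconsistent(rows, 1, "22")


def _single_stratum_rows(p, n_pairs=50, n_extra=0):
    """Pairs with identical |dR| and a fixed fraction of low-mean choices."""
    recs = []
    k_low = int(round(p * (2 * n_pairs + n_extra)))
    i = 0
    for k in range(n_pairs):
        for member in (1, 2):
            recs.append(
                dict(horizon=1, info_condition="22", pair_id=f"p{k}",
                     delta_R=8.0, chose_low_mean=i < k_low,
                     chose_right=False, game_id=f"{k}_{member}")
            )
            i += 1
    for j in range(n_extra):
        recs.append(
            dict(horizon=1, info_condition="22", pair_id="",
                 delta_R=8.0, chose_low_mean=i < k_low, chose_right=False,
                 game_id=f"u{j}")
        )
        i += 1
    return rows_frame(recs)


class TestPureRandomPrediction:
    def test_single_stratum_plug_in_enumeration(self):
        # two independent choices with p = 0.2: inconsistency 2*0.2*0.8
        rows = _single_stratum_rows(0.2)
        pred = pure_random_prediction(rows, 1, "22", bias_corrected=False)
        assert pred == pytest.approx(0.32)

    def test_extremes(self):
        assert pure_random_prediction(
            _single_stratum_rows(0.0), 1, "22"
        ) == pytest.approx(0.0)
        assert pure_random_prediction(
            _single_stratum_rows(0.5), 1, "22"
        ) == pytest.approx(0.5)  # corrected value is clipped at the bound

    @settings(max_examples=30, deadline=None)
    @given(p=st.floats(0.0, 1.0), n_pairs=st.integers(2, 40))
    def test_never_exceeds_half(self, p, n_pairs):
        pred = pure_random_prediction(_single_stratum_rows(p, n_pairs), 1, "22")
        assert 0.0 <= pred <= 0.5 + 1e-12

    def test_merging_equal_p_strata_is_invariant(self):
        """Strata with identical p can be merged without changing the
        plug-in mixture."""
        recs = []
        i = 0
        for dr, tag in ((4.0, "a"), (16.0, "b")):
            for k in range(10):
                for member in (1, 2):
                    recs.append(
                        dict(horizon=1, info_condition="22",
                             pair_id=f"{tag}{k}", delta_R=dr,
                             chose_low_mean=(i % 5 == 0), chose_right=False,
                             game_id=f"{tag}{k}_{member}")
                    )
                    i += 1
        rows = rows_frame(recs)
        split = pure_random_prediction(rows, 1, "22", n_bins=2, bias_corrected=False)
        merged = pure_random_prediction(rows, 1, "22", n_bins=1, bias_corrected=False)
        assert split == pytest.approx(merged)

    def test_null_control_is_unbiased(self, rng):
        """Under truly independent (pure random) choices, prediction and
        observed inconsistency agree in expectation."""
        n_pairs, reps = 40, 40
        diffs = []
        for _ in range(reps):
            recs = []
            for k in range(n_pairs):
                dr = rng.choice([4.0, 8.0, 12.0, 20.0])
                p = 1 / (1 + np.exp(dr / 6.0))  # p(low mean) given |dR|
                for member in (1, 2):
                    low = bool(rng.random() < p)
                    recs.append(
                        dict(horizon=1, info_condition="22", pair_id=f"p{k}",
                             delta_R=dr, chose_low_mean=low, chose_right=low,
                             game_id=f"{k}_{member}")
                    )
            rows = rows_frame(recs)
            diffs.append(
                p_inconsistent(rows, 1, "22")
                - pure_random_prediction(rows, 1, "22")
            )
        t, p = sps.ttest_1samp(diffs, 0.0)
        assert p > 0.01


class TestHorizonContrast:
    def _table(self, h1, h6):
        recs = []
        for i, (a, b) in enumerate(zip(h1, h6)):
            recs.append(dict(subject_id=f"s{i}", horizon=1, stat=a))
            recs.append(dict(subject_id=f"s{i}", horizon=6, stat=b))
        return pd.DataFrame(recs)

    def test_no_difference_gives_zero_t(self):
        t = self._table([0.2, 0.3, 0.4], [0.2, 0.3, 0.4])
        res = horizon_contrast(t, "stat")
        assert res.t == 0.0 and res.p == 1.0

    def test_constant_shift_is_degenerate(self):
        t = self._table([0.2, 0.3, 0.4], [0.3, 0.4, 0.5])
        res = horizon_contrast(t, "stat")
        assert res.degenerate and np.isinf(res.t) and res.t > 0

    def test_matches_scipy(self, rng):
        h1 = rng.normal(0.2, 0.05, 20)
        h6 = rng.normal(0.3, 0.05, 20)
        res = horizon_contrast(self._table(h1, h6), "stat")
        ref = sps.ttest_rel(h6, h1)
        assert res.t == pytest.approx(float(ref.statistic))
        assert res.p == pytest.approx(float(ref.pvalue))
        assert res.df == 19

    def test_power_against_closed_form(self, rng):
        """Rejection rate under a known shift reaches the analytic paired-t
        power (within Monte-Carlo error)."""
        n, d, reps = 12, 0.9, 300
        rejections = 0
        for _ in range(reps):
            diff = rng.normal(d, 1.0, n)
            t = self._table(np.zeros(n), diff)
            rejections += horizon_contrast(t, "stat").p < 0.05
        nc = d * np.sqrt(n)
        tcrit = sps.t.ppf(0.975, n - 1)
        power = 1 - sps.nct.cdf(tcrit, n - 1, nc) + sps.nct.cdf(-tcrit, n - 1, nc)
        se = np.sqrt(power * (1 - power) / reps)
        assert abs(rejections / reps - power) < 4 * se


class TestExclusion:
    def _subject_trials(self, subject, n_games, n_correct):
        games = []
        for g in range(n_games):
            correct_side = "right"  # mean_right higher
            side5to9 = ["left"] * 5
            last = correct_side if g < n_correct else "left"
            rows = make_game_rows(
                subject=subject, game_id=g, horizon=6, info="22",
                forced_sides=("left", "left", "right", "right"),
                forced_rewards=(40, 42, 58, 60),
                free_sides=tuple(side5to9 + [last]),
            )
            for r in rows:
                r["mean_left"], r["mean_right"] = 40.0, 60.0
            games.append(rows)
        return trials_frame(*games)

    @pytest.mark.parametrize(
        "n_correct, expected_kept",
        [(60, True), (30, False)],
    )
    def test_clear_cases(self, n_correct, expected_kept):
        trials = self._subject_trials("s0", 60, n_correct)
        report = exclude_subjects(trials)
        assert bool(report.loc[0, "kept"]) is expected_kept

    def test_threshold_case_matches_exact_binomial(self):
        trials = self._subject_trials("s0", 60, 41)
        report = exclude_subjects(trials)
        exact = sps.binom.sf(40, 60, 0.5)
        assert report.loc[0, "p_value"] == pytest.approx(exact)
        assert bool(report.loc[0, "kept"]) is bool(exact < 0.001)

    def test_no_horizon6_games_excluded_with_reason(self, game_rows_factory):
        trials = trials_frame(game_rows_factory(horizon=1))
        report = exclude_subjects(trials)
        assert not report.loc[0, "kept"]
        assert "no horizon-6" in report.loc[0, "reason"]


def test_subject_stats_has_all_cells(small_trials):
    from dualnoise import first_free_choices

    table = subject_stats(first_free_choices(small_trials))
    assert set(table["horizon"]) == {1, 6}
    for col in (
        "p_low_mean", "p_high_info", "p_inconsistent_13", "p_inconsistent_22",
        "predicted_inconsistent_random_13", "predicted_inconsistent_random_22",
    ):
        assert col in table.columns
    assert (table["predicted_inconsistent_deterministic_22"] == 0).all()
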