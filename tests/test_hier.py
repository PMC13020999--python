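"""Hierarchical model: likelihoods, variants, prior identities, sampler."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from scipy.special import log_expit

from dualnoise import (
    ConfigurationError,
    HyperPriorConfig,
    SubjectParams,
    build_posterior,
    marginal_pair_likelihood,
    model_variants,
    pair_log_likelihood,
    pair_agreement_prob,
    run_mcmc,
)
from dualnoise.mcmc import MCMCConfig


def pair_frame(specs):
    """specs: list of (delta_R, delta_I, chose_right)."""
    return pd.DataFrame(
        [dict(delta_R=dr, delta_I=di, chose_right=cr) for dr, di, cr in specs]
    )


def toy_rows(n_subjects=2, pairs_per_horizon=3, seed=0):
    rng = np.random.default_rng(seed)
    recs = []
    for s in range(n_subjects):
        g = 0
        for h in (1, 6):
            for p in range(pairs_per_horizon):
                dr = float(rng.normal(0, 10))
                di = int(rng.choice([-1, 0, 1]))
                for member in (1, 2):
                    recs.append(
                        dict(subject_id=f"s{s}", game_id=g, pair_id=f"p{h}_{p}",
                             horizon=h, info_condition="22" if di == 0 else "13",
                             delta_R=dr, delta_I=di,
                             var_left=1.0, var_right=1.0,
                             chose_right=bool(rng.integers(2)))
                    )
                    g += 1
    return pd.DataFrame(recs)


class TestPairLogLikelihood:
    def test_symmetric_drive_gives_half_per_game(self):
        p = SubjectParams(sigma_ran=3.0)
        rows = pair_frame([(0.0, 0, True), (0.0, 0, False)])
        assert pair_log_likelihood(p, 0.0, rows) == pytest.approx(2 * np.log(0.5))

    def test_unit_drive_closed_form(self):
        p = SubjectParams(sigma_ran=2.0)
        rows = pair_frame([(2.0, 0, True)])
        assert pair_log_likelihood(p, 0.0, rows) == pytest.approx(
            float(log_expit(1.0))
        )

    def test_impossible_choice_without_random_noise(self):
        p = SubjectParams(sigma_ran=0.0)
        rows = pair_frame([(5.0, 0, False)])
        assert pair_log_likelihood(p, 0.0, rows) == -np.inf

    @settings(max_examples=50, deadline=None)
    @given(
        dr=st.floats(-20, 20), di=st.sampled_from([-1.0, 0.0, 1.0]),
        b=st.floats(-3, 3), A=st.floats(-3, 3), nd=st.floats(-4, 4),
        sr=st.floats(0.3, 8), c1=st.booleans(), c2=st.booleans(),
    )
    def test_left_right_flip_symmetry(self, dr, di, b, A, nd, sr, c1, c2):
        """Mirroring the task (sides, bias, reward and info differences,
        frozen noise) leaves the likelihood unchanged."""
        p = SubjectParams(A=A, b=b, sigma_ran=sr)
        q = SubjectParams(A=A, b=-b, sigma_ran=sr)
        rows = pair_frame([(dr, di, c1), (dr, di, c2)])
        flipped = pair_frame([(-dr, -di, not c1), (-dr, -di, not c2)])
        assert pair_log_likelihood(p, nd, rows) == pytest.approx(
            pair_log_likelihood(q, -nd, flipped), rel=1e-12
        )

    def test_quadrature_agreement_matches_monte_carlo(self, rng):
        """Marginal within-pair agreement: quadrature over the frozen noise
        vs brute-force noise simulation."""
        p = SubjectParams(A=1.0, b=0.5, sigma_det=2.0, sigma_ran=3.0)
        dr, di = 4.0, 1.0
        both = (
            marginal_pair_likelihood(p, pair_frame([(dr, di, True)] * 2))
            + marginal_pair_likelihood(p, pair_frame([(dr, di, False)] * 2))
        )
        assert both == pytest.approx(pair_agreement_prob(p, dr, di), abs=1e-6)
        n = 400_000
        nd = rng.logistic(0, p.sigma_det, n)
        pr = 1 / (1 + np.exp(-(dr + p.A * di + p.b + nd) / p.sigma_ran))
        mc = np.mean(pr**2 + (1 - pr) ** 2)
        assert both == pytest.approx(mc, abs=4 * np.std(pr**2 + (1 - pr) ** 2) / np.sqrt(n))


class TestBuildPosterior:
    def test_drops_subject_missing_horizon(self):
        rows = toy_rows()
        rows = pd.concat(
            [rows, rows[rows.subject_id == "s0"].iloc[:2].assign(subject_id="s9")],
            ignore_index=True,
        )
        with pytest.warns(UserWarning, match="s9"):
            post = build_posterior(rows)
        assert "s9" not in post.subjects

    def test_units_shared_within_pairs(self):
        post = build_posterior(toy_rows())
        # each pair contributes one unit shared by its two observations
        assert post.n_units == post.n_obs // 2

    def test_variant_validation(self):
        with pytest.raises(ConfigurationError):
            build_posterior(toy_rows(), variants={"no_det", "det_fixed_across_horizon"})
        with pytest.raises(ConfigurationError):
            build_posterior(toy_rows(), variants={"bogus"})

    def test_no_flags_is_identity(self):
        a = build_posterior(toy_rows())
        b = model_variants(toy_rows(), ())
        np.testing.assert_array_equal(a.o_dI, b.o_dI)
        assert a.nd == b.nd and a.nr == b.nr
        assert a.include_det and a.include_ran

    def test_variance_dI_with_equal_variances_is_zero(self):
        post = model_variants(toy_rows(), {"variance_dI"})
        np.testing.assert_allclose(post.o_dI, 0.0)

    def test_sigma_by_info_slot_structure(self):
        post = build_posterior(toy_rows(), variants={"sigma_by_info"})
        assert post.nd == 4 and post.nr == 4
        post2 = build_posterior(
            toy_rows(), variants={"sigma_by_info", "det_fixed_across_horizon"}
        )
        assert post2.nd == 2  # info only

    def test_fixed_across_horizon_ties_slots(self):
        post = build_posterior(toy_rows(), variants={"ran_fixed_across_horizon"})
        assert post.nr == 1 and post.nd == 2


FIXED = dict(
    mu_A=0.5, sd_A=2.0, mu_b=0.0, sd_b=1.0,
    k_det=2.0, lam_det=1.0, k_ran=3.0, lam_ran=1.0,
)


class TestSampler:
    def test_same_seed_reproduces_draws(self):
        post = build_posterior(toy_rows())
        cfg = MCMCConfig(chains=2, samples=50, burnin=50, seed=4)
        a = run_mcmc(post, cfg)
        b = run_mcmc(post, cfg)
        for name in a.params:
            np.testing.assert_array_equal(a.params[name], b.params[name])

    def test_prior_only_fixed_hypers_recovers_closed_form_priors(self):
        """Zero-data posterior with pinned hyperparameters = the prior:
        marginal quantiles match the closed-form Gaussian/Gamma."""
        post = build_posterior(toy_rows(), fixed_hypers=FIXED, prior_only=True)
        draws = run_mcmc(post, MCMCConfig(chains=4, samples=3000, burnin=1500, seed=6))
        qs = [0.1, 0.25, 0.5, 0.75, 0.9]
        A = draws.params["A"].ravel()
        for q, ref in zip(qs, sps.norm(0.5, 2.0).ppf(qs)):
            assert np.quantile(A, q) == pytest.approx(ref, abs=0.12)
        sd = draws.params["sigma_det"].ravel()
        for q, ref in zip(qs, sps.gamma(2.0, scale=1.0).ppf(qs)):
            assert np.quantile(sd, q) == pytest.approx(ref, rel=0.08, abs=0.05)
        sr = draws.params["sigma_ran"].ravel()
        for q, ref in zip(qs, sps.gamma(3.0, scale=1.0).ppf(qs)):
            assert np.quantile(sr, q) == pytest.approx(ref, rel=0.08, abs=0.05)

    def test_prior_only_free_hypers_recovers_hyperpriors(self):
        """With free hyperparameters and no data, the group-level marginals
        equal their hyperpriors (narrow configuration)."""
        post = build_posterior(
            toy_rows(), hyper=HyperPriorConfig.narrow(), prior_only=True
        )
        draws = run_mcmc(post, MCMCConfig(chains=4, samples=4000, burnin=2000, seed=9))
        muA = draws.params["mu_A"].ravel()
        assert np.mean(muA) == pytest.approx(0.0, abs=0.5)
        assert np.std(muA) == pytest.approx(10.0, rel=0.05)
        sdA = draws.params["sd_A"].ravel()
        for q in (0.25, 0.5, 0.75):
            assert np.quantile(sdA, q) == pytest.approx(
                sps.expon(scale=10.0).ppf(q), rel=0.12
            )
        lam = draws.params["lam_det"].ravel()
        assert np.median(lam) == pytest.approx(
            sps.expon(scale=0.1).ppf(0.5), rel=0.12
        )

    def test_gaussian_toy_target_moments(self):
        """Prior-only single-parameter target N(0.5, 2): sample moments match
        within Monte-Carlo standard error."""
        import arviz as az

        post = build_posterior(toy_rows(), fixed_hypers=FIXED, prior_only=True)
        draws = run_mcmc(post, MCMCConfig(chains=4, samples=3000, burnin=1500, seed=2))
        A = draws.params["A"][:, :, 0, 0]
        ess = float(az.ess(np.asarray(A), method="bulk"))
        mcse = 2.0 / np.sqrt(ess)
        assert abs(A.mean() - 0.5) < 3 * mcse
        assert A.var() == pytest.approx(4.0, rel=0.15)

    def test_impossible_pair_without_random_noise_raises(self):
        rows = pair_frame([(5.0, 0, True), (5.0, 0, False)]).assign(
            subject_id="s0", game_id=[0, 1], pair_id="p0", horizon=1,
            info_condition="22",
        )
        rows = pd.concat([rows, rows.assign(horizon=6, pair_id="p1", game_id=[2, 3])])
        post = build_posterior(rows, variants={"no_ran"})
        from dualnoise import DataError

        with pytest.raises(DataError):
            run_mcmc(post, MCMCConfig(chains=2, samples=20, burnin=20, seed=0))

    def test_no_ran_variant_fits_consistent_data(self):
        rows = pair_frame([(5.0, 0, True), (5.0, 0, True)]).assign(
            subject_id="s0", game_id=[0, 1], pair_id="p0", horizon=1,
            info_condition="22",
        )
        rows = pd.concat(
            [rows, rows.assign(horizon=6, pair_id="p1", game_id=[2, 3])],
            ignore_index=True,
        )
        post = build_posterior(rows, variants={"no_ran"}, fixed_hypers=FIXED)
        draws = run_mcmc(post, MCMCConfig(chains=2, samples=200, burnin=200, seed=3))
        assert "sigma_ran" not in draws.params
        assert np.isfinite(draws.params["sigma_det"]).all()


def test_no_det_variant_matches_full_model_limit_on_det_free_data():
    """Data generated without frozen noise: the reduced no-frozen-noise fit
    and the full fit agree on the random-noise scale (the full model's
    sigma_det posterior collapses toward zero)."""
    import dualnoise.validation as dv
    from dualnoise.task import TaskConfig, first_free_choices

    rng = np.random.default_rng(14)
    grid = np.linspace(2, 6, 10)
    recs = []
    for h in (1, 6):
        for s in range(10):
            recs.append(
                dict(subject_id=f"s{s:02d}", horizon=h, A=rng.normal(1, 1),
                     b=rng.normal(0, 1), sigma_det=0.0,
                     sigma_ran=float(grid[s]))
            )
    truths = pd.DataFrame(recs)
    trials, _ = dv.simulate_cohort(truths, TaskConfig(), 14)
    rows = first_free_choices(trials)
    cfg = MCMCConfig(chains=2, samples=500, burnin=500, seed=14)
    full = run_mcmc(build_posterior(rows), cfg)
    reduced = run_mcmc(build_posterior(rows, variants={"no_det"}), cfg)
    sr_full = full.params["sigma_ran"].mean(axis=(0, 1))
    sr_red = reduced.params["sigma_ran"].mean(axis=(0, 1))
    assert np.median(np.abs(sr_full - sr_red) / sr_red) < 0.2
    assert float(full.params["sigma_det"].mean()) < 1.5
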