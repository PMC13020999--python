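"""Blocked Metropolis-within-Gibbs sampler for the hierarchical model.

The posterior factorizes into conditionally independent blocks — per-pair
latent frozen-noise values, per-subject parameters, and group-level
hyperparameters — which are updated in turn with random-walk Metropolis
steps (Gibbs for the conjugate Gaussian group means), all chains advancing
together as a leading numpy axis.  Proposal scales adapt toward a 0.44
acceptance rate during burn-in only, so the post-burn-in chain is a valid
time-homogeneous Markov chain.  Positive parameters are proposed on the log
scale with the Jacobian correction.

Gamma shape/rate pairs mix slowly under coordinate-wise moves because the
posterior concentrates along ridges of constant mean k/lam; a third "ridge"
move that scales shape and rate jointly handles this.

Hierarchical scale parameters form funnels (group SD small -> subject values
pinned near the mean) in which centered coordinate-wise updates stall.  The
sampler therefore interweaves non-centered moves: joint shifts of a group
mean with all its subject values, joint rescaling of a group SD with its
centered subject deviations, joint rescaling of a subject's frozen-noise
scale with that subject's latent draws, and a group-level scale move that
rescales every subject sigma together with the Gamma rate (and, for the
frozen noise, the latents).  Each is a plain Metropolis move in the
transformed coordinates with the appropriate Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, log_expit

from ._exceptions import ConfigurationError, DataError
from .hier import Posterior

__all__ = ["MCMCConfig", "PosteriorDraws", "run_mcmc"]

_LOG_HALF = float(np.log(0.5))
_TARGET_ACC = 0.44
_ADAPT_RATE = 0.08

GROUP_PARAMS = ("mu_A", "sd_A", "mu_b", "sd_b", "k_det", "lam_det", "k_ran", "lam_ran")
SUBJECT_PARAMS = ("A", "b", "sigma_det", "sigma_ran")


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.  Defaults mirror the study's fits: 10 chains of
    5000 kept samples each after 5000 burn-in, thin 1."""

    chains: int = 10
    samples: int = 5000
    burnin: int = 5000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 1 or self.samples < 1 or self.burnin < 0 or self.thin < 1:
            raise ConfigurationError("invalid MCMC configuration")


@dataclass
class PosteriorDraws:
    """MCMC output: parameter arrays shaped (chain, draw, ...)."""

    params: dict
    posterior: Posterior
    config: MCMCConfig

    @property
    def chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def subject_means(self, name: str) -> pd.DataFrame:
        """Posterior mean of a subject-level parameter, one row per subject,
        one column per slot (labelled by horizon when slots are horizons)."""
        arr = self.params[name]  # (C, D, S, n)
        means = arr.mean(axis=(0, 1))
        labels = {
            "A": self.posterior.slotA_labels,
            "b": self.posterior.slotA_labels,
            "sigma_det": self.posterior.slotd_labels,
            "sigma_ran": self.posterior.slotr_labels,
        }[name]
        cols = []
        for h, info in labels:
            tag = "" if h is None else f"h{self.posterior.horizons[h]}"
            tag += "" if info is None else f"i{info}"
            cols.append(tag or "all")
        return pd.DataFrame(means, index=self.posterior.subjects, columns=cols)

    def group_noise_mean(self, which: str) -> np.ndarray:
        """Per-draw group-level mean noise scale k/lam, shape (C, D, slots)."""
        return self.params[f"k_{which}"] / self.params[f"lam_{which}"]

    def to_inference_data(self):
        """Convert to an :mod:`arviz` InferenceData for diagnostics."""
        import arviz as az

        return az.from_dict(posterior=self.params)

    def flat(self) -> dict:
        """Flatten every scalar component to name -> (C, D) arrays."""
        out = {}
        for name, arr in self.params.items():
            if arr.ndim == 2:
                out[name] = arr
            elif arr.ndim == 3:
                for j in range(arr.shape[2]):
                    out[f"{name}[{j}]"] = arr[:, :, j]
            else:
                for s in range(arr.shape[2]):
                    for j in range(arr.shape[3]):
                        out[f"{name}[{s},{j}]"] = arr[:, :, s, j]
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format (chain, draw, parameter, value) table."""
        recs = []
        for name, arr in self.flat().items():
            c, d = np.meshgrid(
                np.arange(arr.shape[0]), np.arange(arr.shape[1]), indexing="ij"
            )
            recs.append(
                pd.DataFrame(
                    {
                        "chain": c.ravel(),
                        "draw": d.ravel(),
                        "parameter": name,
                        "value": arr.ravel(),
                    }
                )
            )
        return pd.concat(recs, ignore_index=True)


def _logistic_lp(x, scale):
    t = np.abs(x) / scale
    return -t - np.log(scale) - 2.0 * np.log1p(np.exp(-t))


def _normal_lp(x, loc, sd):
    return -0.5 * ((x - loc) / sd) ** 2 - np.log(sd)


def _gamma_lp(x, k, rate):
    with np.errstate(divide="ignore", invalid="ignore"):
        return (k - 1.0) * np.log(x) - rate * x + k * np.log(rate) - gammaln(k)


class _Sampler:
    def __init__(self, post: Posterior, cfg: MCMCConfig):
        self.post = post
        self.cfg = cfg
        self.C = cfg.chains
        self.rng = np.random.default_rng(
            np.random.SeedSequence([int(cfg.seed) & 0x7FFFFFFF, 0x0D0A])
        )
        C, S, U, O = self.C, post.S, post.n_units, post.n_obs
        self.conv = post.scale_conv

        # precomputed segment indices (fixed across iterations)
        self.ix_obs_unit = o = post.o_unit
        self.flat_unit = (np.arange(C)[:, None] * U + o).ravel() if U else None
        self.ix_subA = post.o_sub * post.nA + post.o_slotA
        self.flat_subA = (np.arange(C)[:, None] * (S * post.nA) + self.ix_subA).ravel()
        self.ix_subr = post.o_sub * post.nr + post.o_slotr
        self.flat_subr = (np.arange(C)[:, None] * (S * post.nr) + self.ix_subr).ravel()
        if U:
            self.ix_unitd = post.u_sub * post.nd + post.u_slotd
            self.flat_unitd = (
                np.arange(C)[:, None] * (S * post.nd) + self.ix_unitd
            ).ravel()
            self.flat_unit_slotd = (
                np.arange(C)[:, None] * post.nd + post.u_slotd
            ).ravel()
            # units per (subject, det-slot) block and per det slot
            self.n_unit_block = np.bincount(
                self.ix_unitd, minlength=S * post.nd
            ).reshape(S, post.nd)
            self.n_unit_slot = np.bincount(post.u_slotd, minlength=post.nd)
        self.flat_obs_subd = (
            np.arange(C)[:, None] * (S * post.nd)
            + (post.o_sub * post.nd + post.o_slotd)
        ).ravel()
        self.flat_obs_slotd = (np.arange(C)[:, None] * post.nd + post.o_slotd).ravel()
        self.flat_obs_slotr = (np.arange(C)[:, None] * post.nr + post.o_slotr).ravel()
        self.flat_obs_slotA = (np.arange(C)[:, None] * post.nA + post.o_slotA).ravel()

        self._init_state()
        self.drive = self._drive()
        self.ll = self._ll(self.drive, self.sr)
        if not np.isfinite(self.ll.sum()):
            raise DataError(
                "zero-likelihood data under the reduced model "
                "(inconsistent choices with no random noise)"
            )

        # adaptive proposal scales
        def full(shape, v):
            return np.full(shape, v, dtype=float)

        self.steps = {
            "nd": full((C, U), 1.0),
            "A": full((C, S, post.nA), 0.6),
            "b": full((C, S, post.nA), 0.6),
            "sd": full((C, S, post.nd), 0.4),
            "sr": full((C, S, post.nr), 0.4),
            "sd_A": full((C, post.nA), 0.4),
            "sd_b": full((C, post.nA), 0.4),
            "k_det": full((C, post.nd), 0.3),
            "lam_det": full((C, post.nd), 0.3),
            "ridge_det": full((C, post.nd), 0.3),
            "k_ran": full((C, post.nr), 0.3),
            "lam_ran": full((C, post.nr), 0.3),
            "ridge_ran": full((C, post.nr), 0.3),
            "nc_mu_A": full((C, post.nA), 0.4),
            "nc_sd_A": full((C, post.nA), 0.3),
            "nc_mu_b": full((C, post.nA), 0.4),
            "nc_sd_b": full((C, post.nA), 0.3),
            "asis_sd": full((C, S, post.nd), 0.3),
            "scale_det": full((C, post.nd), 0.2),
            "scale_ran": full((C, post.nr), 0.2),
        }

    # ---------------------------------------------------------------- state
    def _init_state(self):
        post, C, rng = self.post, self.C, self.rng
        S, U = post.S, post.n_units
        self.A = rng.normal(0.0, 1.0, (C, S, post.nA))
        self.b = rng.normal(0.0, 1.0, (C, S, post.nA))
        self.sd = np.exp(rng.normal(np.log(1.5), 0.5, (C, S, post.nd)))
        self.sr = np.exp(rng.normal(np.log(3.0), 0.5, (C, S, post.nr)))
        if post.fixed_hypers:
            fh = post.fixed_hypers

            def get(name, n):
                return np.broadcast_to(
                    np.asarray(fh[name], dtype=float), (C, n)
                ).copy()

            self.muA, self.sdA = get("mu_A", post.nA), get("sd_A", post.nA)
            self.mub, self.sdb = get("mu_b", post.nA), get("sd_b", post.nA)
            self.kd, self.ld = get("k_det", post.nd), get("lam_det", post.nd)
            self.kr, self.lr = get("k_ran", post.nr), get("lam_ran", post.nr)
        else:
            self.muA = rng.normal(0.0, 0.5, (C, post.nA))
            self.sdA = np.exp(rng.normal(0.0, 0.3, (C, post.nA)))
            self.mub = rng.normal(0.0, 0.5, (C, post.nA))
            self.sdb = np.exp(rng.normal(0.0, 0.3, (C, post.nA)))
            self.kd = np.exp(rng.normal(np.log(2.0), 0.3, (C, post.nd)))
            self.ld = self.kd / np.maximum(self.sd.mean(axis=1), 0.2)
            self.kr = np.exp(rng.normal(np.log(2.0), 0.3, (C, post.nr)))
            self.lr = self.kr / np.maximum(self.sr.mean(axis=1), 0.2)

        if post.include_det:
            scale = self.sd[:, post.u_sub, post.u_slotd] * self.conv
            self.ndet = rng.logistic(0.0, 1.0, (C, U)) * scale
            if not post.include_ran:
                self._feasible_ndet()
        else:
            self.ndet = np.zeros((C, U))

    def _feasible_ndet(self):
        """With no random noise the choice rule is a hard threshold; start
        every latent inside its feasible interval (or fail if none exists)."""
        post, C = self.post, self.C
        base = (
            post.o_dR
            + self.A[:, post.o_sub, post.o_slotA] * post.o_dI
            + self.b[:, post.o_sub, post.o_slotA]
        )
        lo = np.full((C, post.n_units), -np.inf)
        hi = np.full((C, post.n_units), np.inf)
        pos = post.o_sgn > 0
        for c in range(C):
            np.maximum.at(lo[c], post.o_unit[pos], -base[c, pos])
            np.minimum.at(hi[c], post.o_unit[~pos], -base[c, ~pos])
        if np.any(lo >= hi):
            # infeasible under these A, b; try A=b=0 geometry before failing
            raise DataError(
                "no frozen-noise value can explain a pair's choices without "
                "random noise"
            )
        mid = np.where(
            np.isfinite(lo) & np.isfinite(hi),
            0.5 * (lo + hi),
            np.where(np.isfinite(lo), lo + 1.0, np.where(np.isfinite(hi), hi - 1.0, 0.0)),
        )
        self.ndet = mid

    # ------------------------------------------------------------ likelihood
    def _drive(self):
        post = self.post
        d = (
            post.o_dR
            + self.A[:, post.o_sub, post.o_slotA] * post.o_dI
            + self.b[:, post.o_sub, post.o_slotA]
        )
        if post.include_det:
            d = d + self.ndet[:, post.o_unit]
        return d

    def _ll(self, drive, sr):
        post = self.post
        if post.include_ran:
            s = sr[:, post.o_sub, post.o_slotr] * self.conv
            with np.errstate(divide="ignore", over="ignore"):
                return log_expit(post.o_sgn * drive / s)
        z = post.o_sgn * drive
        return np.where(z > 0, 0.0, np.where(z == 0, _LOG_HALF, -np.inf))

    def _seg(self, vals, flat_idx, n):
        return np.bincount(flat_idx, weights=vals.ravel(), minlength=self.C * n).reshape(
            self.C, n
        )

    def _accept(self, delta):
        return np.log(self.rng.random(delta.shape)) < delta

    def _adapt(self, key, acc, adapting):
        if adapting:
            s = self.steps[key] * np.exp(_ADAPT_RATE * (acc - _TARGET_ACC))
            self.steps[key] = np.clip(s, 1e-4, 50.0)

    # --------------------------------------------------------------- blocks
    def update_ndet(self, adapting):
        post, C = self.post, self.C
        U = post.n_units
        prop = self.ndet + self.steps["nd"] * self.rng.standard_normal((C, U))
        new_drive = self.drive + (prop - self.ndet)[:, post.o_unit]
        new_ll = self._ll(new_drive, self.sr)
        d_ll = self._seg(new_ll - self.ll, self.flat_unit, U)
        scale = self.sd[:, post.u_sub, post.u_slotd] * self.conv
        d_pr = _logistic_lp(prop, scale) - _logistic_lp(self.ndet, scale)
        acc = self._accept(d_ll + d_pr)
        self.ndet = np.where(acc, prop, self.ndet)
        m = acc[:, post.o_unit]
        self.drive = np.where(m, new_drive, self.drive)
        self.ll = np.where(m, new_ll, self.ll)
        self._adapt("nd", acc, adapting)

    def _update_location(self, name, adapting):
        """RW-MH on A or b (slope on dI for A, intercept for b)."""
        post, C, S = self.post, self.C, self.post.S
        cur = self.A if name == "A" else self.b
        mu = self.muA if name == "A" else self.mub
        sd = self.sdA if name == "A" else self.sdb
        prop = cur + self.steps[name] * self.rng.standard_normal(cur.shape)
        diff = (prop - cur)[:, post.o_sub, post.o_slotA]
        if name == "A":
            diff = diff * post.o_dI
        new_drive = self.drive + diff
        new_ll = self._ll(new_drive, self.sr)
        d_ll = self._seg(new_ll - self.ll, self.flat_subA, S * post.nA).reshape(
            C, S, post.nA
        )
        d_pr = _normal_lp(prop, mu[:, None, :], sd[:, None, :]) - _normal_lp(
            cur, mu[:, None, :], sd[:, None, :]
        )
        acc = self._accept(d_ll + d_pr)
        new = np.where(acc, prop, cur)
        if name == "A":
            self.A = new
        else:
            self.b = new
        m = acc[:, post.o_sub, post.o_slotA]
        self.drive = np.where(m, new_drive, self.drive)
        self.ll = np.where(m, new_ll, self.ll)
        self._adapt(name, acc, adapting)

    def update_sigma_ran(self, adapting):
        post, C, S = self.post, self.C, self.post.S
        prop = np.maximum(
            self.sr
            * np.exp(self.steps["sr"] * self.rng.standard_normal(self.sr.shape)),
            1e-12,
        )
        new_ll = self._ll(self.drive, prop)
        d_ll = self._seg(new_ll - self.ll, self.flat_subr, S * post.nr).reshape(
            C, S, post.nr
        )
        kr, lr = self.kr[:, None, :], self.lr[:, None, :]
        d_pr = (
            _gamma_lp(prop, kr, lr)
            - _gamma_lp(self.sr, kr, lr)
            + np.log(prop)
            - np.log(self.sr)
        )
        acc = self._accept(d_ll + d_pr)
        self.sr = np.where(acc, prop, self.sr)
        m = acc[:, post.o_sub, post.o_slotr]
        self.ll = np.where(m, new_ll, self.ll)
        self._adapt("sr", acc, adapting)

    def update_sigma_det(self, adapting):
        post, C, S = self.post, self.C, self.post.S
        prop = np.maximum(
            self.sd
            * np.exp(self.steps["sd"] * self.rng.standard_normal(self.sd.shape)),
            1e-12,
        )
        s_old = self.sd[:, post.u_sub, post.u_slotd] * self.conv
        s_new = prop[:, post.u_sub, post.u_slotd] * self.conv
        d_lat = self._seg(
            _logistic_lp(self.ndet, s_new) - _logistic_lp(self.ndet, s_old),
            self.flat_unitd,
            S * post.nd,
        ).reshape(C, S, post.nd)
        kd, ld = self.kd[:, None, :], self.ld[:, None, :]
        d_pr = (
            _gamma_lp(prop, kd, ld)
            - _gamma_lp(self.sd, kd, ld)
            + np.log(prop)
            - np.log(self.sd)
        )
        acc = self._accept(d_lat + d_pr)
        self.sd = np.where(acc, prop, self.sd)
        self._adapt("sd", acc, adapting)

    def _update_gaussian_hypers(self, values, mu, sd, mu_name, sd_name, adapting):
        post, C, S = self.post, self.C, self.post.S
        hp = post.hyper
        # conjugate Gibbs draw for the group mean
        prec = S / sd**2 + 1.0 / hp.mu_sd**2
        mean = (values.sum(axis=1) / sd**2 + hp.mu_loc / hp.mu_sd**2) / prec
        mu[...] = mean + self.rng.standard_normal(mu.shape) / np.sqrt(prec)
        # log-RW MH for the group SD
        prop = sd * np.exp(self.steps[sd_name] * self.rng.standard_normal(sd.shape))
        d = (
            (
                _normal_lp(values, mu[:, None, :], prop[:, None, :])
                - _normal_lp(values, mu[:, None, :], sd[:, None, :])
            ).sum(axis=1)
            - hp.sd_rate * (prop - sd)
            + np.log(prop)
            - np.log(sd)
        )
        acc = self._accept(d)
        sd[...] = np.where(acc, prop, sd)
        self._adapt(sd_name, acc, adapting)

    def _update_gamma_hypers(self, values, k, lam, tag, adapting):
        post, C, S = self.post, self.C, self.post.S
        hp = post.hyper
        sumlog = np.log(values).sum(axis=1)
        sumv = values.sum(axis=1)

        def loglik(kk, ll):
            return (
                (kk - 1.0) * sumlog
                - ll * sumv
                + S * (kk * np.log(ll) - gammaln(kk))
            )

        for move in (f"k_{tag}", f"lam_{tag}", f"ridge_{tag}"):
            eps = self.steps[move] * self.rng.standard_normal(k.shape)
            if move.startswith("k"):
                kk, ll, jac = k * np.exp(eps), lam, eps
                d_pr = -hp.k_rate * (kk - k)
            elif move.startswith("lam"):
                kk, ll, jac = k, lam * np.exp(eps), eps
                d_pr = -hp.lam_rate * (ll - lam)
            else:
                kk, ll, jac = k * np.exp(eps), lam * np.exp(eps), 2.0 * eps
                d_pr = -hp.k_rate * (kk - k) - hp.lam_rate * (ll - lam)
            d = loglik(kk, ll) - loglik(k, lam) + d_pr + jac
            acc = self._accept(d)
            k[...] = np.where(acc, kk, k)
            lam[...] = np.where(acc, ll, lam)
            self._adapt(move, acc, adapting)

    # ---------------------------------------------------- interweaved moves
    def _nc_shift(self, name, adapting):
        """Shift a group mean together with all its subject values."""
        post, hp = self.post, self.post.hyper
        cur = self.A if name == "A" else self.b
        mu = self.muA if name == "A" else self.mub
        key = f"nc_mu_{name}"
        eps = self.steps[key] * self.rng.standard_normal(mu.shape)  # (C, n)
        eps_obs = eps[:, post.o_slotA]
        if name == "A":
            eps_obs = eps_obs * post.o_dI
        new_drive = self.drive + eps_obs
        new_ll = self._ll(new_drive, self.sr)
        d_ll = self._seg(new_ll - self.ll, self.flat_obs_slotA, post.nA)
        d_hyp = _normal_lp(mu + eps, hp.mu_loc, hp.mu_sd) - _normal_lp(
            mu, hp.mu_loc, hp.mu_sd
        )
        acc = self._accept(d_ll + d_hyp)
        new_mu = np.where(acc, mu + eps, mu)
        new_cur = np.where(acc[:, None, :], cur + eps[:, None, :], cur)
        if name == "A":
            self.muA, self.A = new_mu, new_cur
        else:
            self.mub, self.b = new_mu, new_cur
        m = acc[:, post.o_slotA]
        self.drive = np.where(m, new_drive, self.drive)
        self.ll = np.where(m, new_ll, self.ll)
        self._adapt(key, acc, adapting)

    def _nc_scale(self, name, adapting):
        """Rescale a group SD together with the centered subject deviations."""
        post, hp, S = self.post, self.post.hyper, self.post.S
        cur = self.A if name == "A" else self.b
        mu = self.muA if name == "A" else self.mub
        sd = self.sdA if name == "A" else self.sdb
        key = f"nc_sd_{name}"
        eps = self.steps[key] * self.rng.standard_normal(sd.shape)  # (C, n)
        f = np.exp(eps)
        prop_sd = sd * f
        prop = mu[:, None, :] + (cur - mu[:, None, :]) * f[:, None, :]
        diff = (prop - cur)[:, post.o_sub, post.o_slotA]
        if name == "A":
            diff = diff * post.o_dI
        new_drive = self.drive + diff
        new_ll = self._ll(new_drive, self.sr)
        d_ll = self._seg(new_ll - self.ll, self.flat_obs_slotA, post.nA)
        d_prior = (
            _normal_lp(prop, mu[:, None, :], prop_sd[:, None, :])
            - _normal_lp(cur, mu[:, None, :], sd[:, None, :])
        ).sum(axis=1)
        d_hyp = -hp.sd_rate * (prop_sd - sd)
        jac = (S + 1.0) * eps
        acc = self._accept(d_ll + d_prior + d_hyp + jac)
        new_sd = np.where(acc, prop_sd, sd)
        new_cur = np.where(acc[:, None, :], prop, cur)
        if name == "A":
            self.sdA, self.A = new_sd, new_cur
        else:
            self.sdb, self.b = new_sd, new_cur
        m = acc[:, post.o_slotA]
        self.drive = np.where(m, new_drive, self.drive)
        self.ll = np.where(m, new_ll, self.ll)
        self._adapt(key, acc, adapting)

    def _asis_sigma_det(self, adapting):
        """Rescale one subject's frozen-noise scale and latent draws jointly."""
        post, C, S = self.post, self.C, self.post.S
        eps = self.steps["asis_sd"] * self.rng.standard_normal(self.sd.shape)
        f = np.exp(eps)
        prop_sd = self.sd * f
        fac_unit = f[:, post.u_sub, post.u_slotd]
        prop_nd = self.ndet * fac_unit
        new_drive = self.drive + (prop_nd - self.ndet)[:, post.o_unit]
        new_ll = self._ll(new_drive, self.sr)
        d_ll = self._seg(new_ll - self.ll, self.flat_obs_subd, S * post.nd).reshape(
            C, S, post.nd
        )
        s_old = self.sd[:, post.u_sub, post.u_slotd] * self.conv
        s_new = prop_sd[:, post.u_sub, post.u_slotd] * self.conv
        d_lat = self._seg(
            _logistic_lp(prop_nd, s_new) - _logistic_lp(self.ndet, s_old),
            self.flat_unitd,
            S * post.nd,
        ).reshape(C, S, post.nd)
        kd, ld = self.kd[:, None, :], self.ld[:, None, :]
        d_pr = _gamma_lp(prop_sd, kd, ld) - _gamma_lp(self.sd, kd, ld)
        jac = (self.n_unit_block[None, :, :] + 1.0) * eps
        acc = self._accept(d_ll + d_lat + d_pr + jac)
        self.sd = np.where(acc, prop_sd, self.sd)
        mu_unit = acc[:, post.u_sub, post.u_slotd]
        self.ndet = np.where(mu_unit, prop_nd, self.ndet)
        m = acc[:, post.o_sub, post.o_slotd]
        self.drive = np.where(m, new_drive, self.drive)
        self.ll = np.where(m, new_ll, self.ll)
        self._adapt("asis_sd", acc, adapting)

    def _scale_group(self, tag, adapting):
        """Rescale every subject sigma of a slot with the Gamma rate (and the
        latents, for the frozen noise): a move along the group-scale ridge."""
        post, C, S = self.post, self.C, self.post.S
        hp = post.hyper
        key = f"scale_{tag}"
        if tag == "det":
            sigma, k, lam, n = self.sd, self.kd, self.ld, post.nd
        else:
            sigma, k, lam, n = self.sr, self.kr, self.lr, post.nr
        eps = self.steps[key] * self.rng.standard_normal(k.shape)  # (C, n)
        f = np.exp(eps)
        prop_sigma = sigma * f[:, None, :]
        prop_lam = lam / f
        d_gamma = (
            _gamma_lp(prop_sigma, k[:, None, :], prop_lam[:, None, :])
            - _gamma_lp(sigma, k[:, None, :], lam[:, None, :])
        ).sum(axis=1)
        d_hyp = -hp.lam_rate * (prop_lam - lam)
        if tag == "det":
            fac_unit = f[:, post.u_slotd]
            prop_nd = self.ndet * fac_unit
            new_drive = self.drive + (prop_nd - self.ndet)[:, post.o_unit]
            new_ll = self._ll(new_drive, self.sr)
            d_ll = self._seg(new_ll - self.ll, self.flat_obs_slotd, post.nd)
            s_old = sigma[:, post.u_sub, post.u_slotd] * self.conv
            s_new = prop_sigma[:, post.u_sub, post.u_slotd] * self.conv
            d_lat = self._seg(
                _logistic_lp(prop_nd, s_new) - _logistic_lp(self.ndet, s_old),
                self.flat_unit_slotd,
                post.nd,
            )
            jac = (S - 1.0 + self.n_unit_slot[None, :]) * eps
            acc = self._accept(d_ll + d_lat + d_gamma + d_hyp + jac)
            self.sd = np.where(acc[:, None, :], prop_sigma, self.sd)
            self.ld = np.where(acc, prop_lam, self.ld)
            self.ndet = np.where(acc[:, post.u_slotd], prop_nd, self.ndet)
            m = acc[:, post.o_slotd]
            self.drive = np.where(m, new_drive, self.drive)
            self.ll = np.where(m, new_ll, self.ll)
        else:
            new_ll = self._ll(self.drive, prop_sigma)
            d_ll = self._seg(new_ll - self.ll, self.flat_obs_slotr, post.nr)
            jac = (S - 1.0) * eps
            acc = self._accept(d_ll + d_gamma + d_hyp + jac)
            self.sr = np.where(acc[:, None, :], prop_sigma, self.sr)
            self.lr = np.where(acc, prop_lam, self.lr)
            m = acc[:, post.o_slotr]
            self.ll = np.where(m, new_ll, self.ll)
        self._adapt(key, acc, adapting)

    # ------------------------------------------------------------------ run
    def iterate(self, adapting):
        post = self.post
        if post.include_det:
            self.update_ndet(adapting)
        self._update_location("A", adapting)
        self._update_location("b", adapting)
        if post.include_ran:
            self.update_sigma_ran(adapting)
        if post.include_det:
            self.update_sigma_det(adapting)
        if post.include_det:
            self._asis_sigma_det(adapting)
        if not post.fixed_hypers:
            self._update_gaussian_hypers(
                self.A, self.muA, self.sdA, "mu_A", "sd_A", adapting
            )
            self._update_gaussian_hypers(
                self.b, self.mub, self.sdb, "mu_b", "sd_b", adapting
            )
            if post.include_det:
                self._update_gamma_hypers(self.sd, self.kd, self.ld, "det", adapting)
            if post.include_ran:
                self._update_gamma_hypers(self.sr, self.kr, self.lr, "ran", adapting)
            self._nc_shift("A", adapting)
            self._nc_shift("b", adapting)
            self._nc_scale("A", adapting)
            self._nc_scale("b", adapting)
            if post.include_det:
                self._scale_group("det", adapting)
            if post.include_ran:
                self._scale_group("ran", adapting)


def run_mcmc(
    posterior: Posterior,
    config: MCMCConfig | None = None,
    store_latents: bool = False,
    **overrides,
) -> PosteriorDraws:
    """Sample the posterior; returns draws shaped (chain, draw, ...).

    ``overrides`` (chains=, samples=, burnin=, thin=, seed=) modify the
    default :class:`MCMCConfig`.  Identical seed and configuration give
    bit-identical draws.
    """
    if config is None:
        config = MCMCConfig(**overrides)
    elif overrides:
        from dataclasses import replace

        config = replace(config, **overrides)

    smp = _Sampler(posterior, config)
    C, D = config.chains, config.samples
    post = posterior
    out = {
        "A": np.empty((C, D, post.S, post.nA)),
        "b": np.empty((C, D, post.S, post.nA)),
    }
    if post.include_det:
        out["sigma_det"] = np.empty((C, D, post.S, post.nd))
        out["k_det"] = np.empty((C, D, post.nd))
        out["lam_det"] = np.empty((C, D, post.nd))
    if post.include_ran:
        out["sigma_ran"] = np.empty((C, D, post.S, post.nr))
        out["k_ran"] = np.empty((C, D, post.nr))
        out["lam_ran"] = np.empty((C, D, post.nr))
    out["mu_A"] = np.empty((C, D, post.nA))
    out["sd_A"] = np.empty((C, D, post.nA))
    out["mu_b"] = np.empty((C, D, post.nA))
    out["sd_b"] = np.empty((C, D, post.nA))
    if store_latents and post.include_det:
        out["n_det"] = np.empty((C, D, post.n_units))

    kept = 0
    total = config.burnin + config.samples * config.thin
    for t in range(total):
        smp.iterate(adapting=t < config.burnin)
        if t >= config.burnin and (t - config.burnin) % config.thin == 0:
            out["A"][:, kept] = smp.A
            out["b"][:, kept] = smp.b
            out["mu_A"][:, kept] = smp.muA
            out["sd_A"][:, kept] = smp.sdA
            out["mu_b"][:, kept] = smp.mub
            out["sd_b"][:, kept] = smp.sdb
            if post.include_det:
                out["sigma_det"][:, kept] = smp.sd
                out["k_det"][:, kept] = smp.kd
                out["lam_det"][:, kept] = smp.ld
                if store_latents:
                    out["n_det"][:, kept] = smp.ndet
            if post.include_ran:
                out["sigma_ran"][:, kept] = smp.sr
                out["k_ran"][:, kept] = smp.kr
                out["lam_ran"][:, kept] = smp.lr
            kept += 1
    for name, arr in out.items():
        if not np.isfinite(arr).all():
            raise DataError(f"non-finite draws in {name}")
    return PosteriorDraws(params=out, posterior=posterior, config=config)
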