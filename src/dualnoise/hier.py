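"""Hierarchical Bayesian model of two-noise choice behavior.

Each subject s in each horizon condition i has four parameters: information
bonus A, spatial bias b, and the logistic scales sigma_det (frozen,
stimulus-driven noise) and sigma_ran (per-play random noise).  Subject-level
parameters are drawn from group-level priors —

    A_is ~ Gaussian(mu_A_i, sd_A_i)        b_is ~ Gaussian(mu_b_i, sd_b_i)
    sigma_det_is ~ Gamma(k_det_i, lam_det_i)   (shape k, *rate* lam, mean k/lam)
    sigma_ran_is ~ Gamma(k_ran_i, lam_ran_i)

— whose hyperparameters carry broad hyperpriors (Gaussian(0, 100) on means,
Exponential(0.01) on group SDs and Gamma shapes, Exponential(10) on Gamma
rates; a narrower variant with Gaussian SD 10 / Exponential(0.1) is available
via :meth:`HyperPriorConfig.narrow`).

The frozen noise enters as an explicit latent variable: one value
``n_det ~ Logistic(0, sigma_det)`` per repeated game pair (shared by both
members) and per unpaired game.  Conditional on it, each first free choice is
Bernoulli with ``P(right) = expit((dR + A*dI + b + n_det) / sigma_ran)``.

Model variants (flags to :func:`build_posterior`): ``sigma_by_info``
(separate noise scales per information condition), ``variance_dI``
(information difference defined as the forced-reward variance difference),
``no_det`` / ``no_ran`` (reduced one-noise models), and
``det_fixed_across_horizon`` / ``ran_fixed_across_horizon`` (noise shared
between horizons).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import log_expit

from ._exceptions import ConfigurationError, DataError
from .agent import LOGISTIC_SD_PER_SCALE, SubjectParams

__all__ = [
    "HyperPriorConfig",
    "VALID_VARIANTS",
    "Posterior",
    "build_posterior",
    "model_variants",
    "pair_log_likelihood",
    "marginal_pair_likelihood",
]

VALID_VARIANTS = frozenset(
    {
        "sigma_by_info",
        "variance_dI",
        "no_det",
        "no_ran",
        "det_fixed_across_horizon",
        "ran_fixed_across_horizon",
    }
)


@dataclass(frozen=True)
class HyperPriorConfig:
    """Hyperprior settings for the group-level parameters.

    ``mu_scale`` is by default the *standard deviation* of the Gaussian
    hyperprior on group means; set ``mu_scale_is_precision`` to reinterpret
    it as a precision when cross-checking against precision-convention
    samplers.
    """

    mu_loc: float = 0.0
    mu_scale: float = 100.0
    sd_rate: float = 0.01
    k_rate: float = 0.01
    lam_rate: float = 10.0
    mu_scale_is_precision: bool = False

    def __post_init__(self) -> None:
        if min(self.mu_scale, self.sd_rate, self.k_rate, self.lam_rate) <= 0:
            raise ConfigurationError("hyperprior scales/rates must be positive")

    @property
    def mu_sd(self) -> float:
        if self.mu_scale_is_precision:
            return float(1.0 / np.sqrt(self.mu_scale))
        return float(self.mu_scale)

    @classmethod
    def broad(cls) -> "HyperPriorConfig":
        """Default broad hyperpriors."""
        return cls()

    @classmethod
    def narrow(cls) -> "HyperPriorConfig":
        """Narrower alternative: Gaussian SD 10 and Exponential(0.1) on SDs."""
        return cls(mu_scale=10.0, sd_rate=0.1)


def _sigma_slots(H: int, infos: list[str], fixed: bool, by_info: bool):
    """Map (horizon index, info index) -> slot column for a noise scale."""
    n_i = len(infos) if by_info else 1
    n_h = 1 if fixed else H
    slot = np.empty((H, len(infos)), dtype=int)
    for h in range(H):
        for i in range(len(infos)):
            slot[h, i] = (0 if fixed else h) * n_i + (i if by_info else 0)
    labels = []
    for h in range(n_h):
        for i in range(n_i):
            labels.append(
                (None if fixed else h, infos[i] if by_info else None)
            )
    return slot, n_h * n_i, labels


@dataclass
class Posterior:
    """A prepared joint posterior: indexed data arrays plus model flags.

    Built by :func:`build_posterior`; consumed by :func:`dualnoise.mcmc.run_mcmc`.
    """

    subjects: list
    horizons: list
    infos: list
    hyper: HyperPriorConfig
    variants: frozenset
    sigma_is_sd: bool
    include_det: bool
    include_ran: bool
    fixed_hypers: dict | None

    # observations (first free choices)
    o_dR: np.ndarray = field(repr=False, default=None)
    o_dI: np.ndarray = field(repr=False, default=None)
    o_sgn: np.ndarray = field(repr=False, default=None)
    o_sub: np.ndarray = field(repr=False, default=None)
    o_unit: np.ndarray = field(repr=False, default=None)
    o_slotA: np.ndarray = field(repr=False, default=None)
    o_slotd: np.ndarray = field(repr=False, default=None)
    o_slotr: np.ndarray = field(repr=False, default=None)

    # latent frozen-noise units (pairs and unpaired games)
    u_sub: np.ndarray = field(repr=False, default=None)
    u_slotd: np.ndarray = field(repr=False, default=None)

    nA: int = 0
    nd: int = 0
    nr: int = 0
    slotA_labels: list = field(default_factory=list)
    slotd_labels: list = field(default_factory=list)
    slotr_labels: list = field(default_factory=list)

    @property
    def S(self) -> int:
        return len(self.subjects)

    @property
    def n_obs(self) -> int:
        return len(self.o_dR)

    @property
    def n_units(self) -> int:
        return len(self.u_sub)

    @property
    def scale_conv(self) -> float:
        """Multiplier turning a sampled sigma into a logistic scale."""
        return 1.0 / LOGISTIC_SD_PER_SCALE if self.sigma_is_sd else 1.0


def _check_variants(variants) -> frozenset:
    flags = frozenset(variants)
    unknown = flags - VALID_VARIANTS
    if unknown:
        raise ConfigurationError(f"unknown model variants: {sorted(unknown)}")
    for noise in ("det", "ran"):
        if f"no_{noise}" in flags and f"{noise}_fixed_across_horizon" in flags:
            raise ConfigurationError(
                f"contradictory flags: no_{noise} with "
                f"{noise}_fixed_across_horizon"
            )
    return flags


def build_posterior(
    rows: pd.DataFrame,
    hyper: HyperPriorConfig | None = None,
    variants=(),
    sigma_is_sd: bool = False,
    fixed_hypers: dict | None = None,
    prior_only: bool = False,
) -> Posterior:
    """Assemble the joint posterior from first-free-choice rows.

    ``rows`` must contain subject_id, pair_id, horizon, info_condition,
    delta_R, delta_I, chose_right (and var_left/var_right for the
    ``variance_dI`` variant).  Subjects missing one of the horizons present
    in the data are dropped with a warning.  ``fixed_hypers`` pins the
    hyperparameters (keys like ``mu_A``, ``sd_A``, ``k_det``, ``lam_det``,
    scalars or per-slot arrays), turning the model into independent
    fixed-prior subject fits — used for oracle cross-checks.  ``prior_only``
    drops every observation (keeping the subject/unit structure), so
    sampling the result recovers the prior — the zero-data identity used to
    validate the sampler.
    """
    hyper = hyper or HyperPriorConfig.broad()
    flags = _check_variants(variants)
    include_det = "no_det" not in flags
    include_ran = "no_ran" not in flags

    rows = rows.copy()
    rows["info_condition"] = rows["info_condition"].astype(str)
    horizons = sorted(rows["horizon"].unique())
    infos = sorted(rows["info_condition"].unique())

    by_subject = rows.groupby("subject_id")["horizon"].agg(lambda h: set(h))
    complete = [s for s, hs in by_subject.items() if hs == set(horizons)]
    dropped = sorted(set(by_subject.index) - set(complete))
    if dropped:
        warnings.warn(f"dropping subjects missing a horizon: {dropped}")
        rows = rows[rows["subject_id"].isin(complete)]
    if not len(rows):
        raise DataError("no subjects with complete horizon coverage")
    subjects = sorted(rows["subject_id"].unique())

    H = len(horizons)
    h_idx = {h: i for i, h in enumerate(horizons)}
    i_idx = {i: j for j, i in enumerate(infos)}
    sub_idx = {s: i for i, s in enumerate(subjects)}

    slotd_map, nd_slots, slotd_labels = _sigma_slots(
        H, infos, "det_fixed_across_horizon" in flags, "sigma_by_info" in flags
    )
    slotr_map, nr_slots, slotr_labels = _sigma_slots(
        H, infos, "ran_fixed_across_horizon" in flags, "sigma_by_info" in flags
    )

    if "variance_dI" in flags:
        if not {"var_left", "var_right"} <= set(rows.columns):
            raise DataError("variance_dI variant needs var_left/var_right columns")
        dI = (rows["var_right"] - rows["var_left"]).to_numpy(dtype=float)
    else:
        dI = rows["delta_I"].to_numpy(dtype=float)

    hv = rows["horizon"].map(h_idx).to_numpy()
    iv = rows["info_condition"].map(i_idx).to_numpy()
    sv = rows["subject_id"].map(sub_idx).to_numpy()

    # frozen-noise units: one per (subject, pair), one per unpaired game
    pair_str = rows["pair_id"].astype(str).replace("nan", "").replace("None", "")
    unit_key = np.where(
        pair_str.str.len() > 0,
        rows["subject_id"].astype(str) + "|p|" + pair_str + "|" + rows["horizon"].astype(str),
        rows["subject_id"].astype(str) + "|g|" + rows["game_id"].astype(str),
    )
    uniq, o_unit = np.unique(unit_key, return_inverse=True)
    U = len(uniq)
    u_sub = np.zeros(U, dtype=int)
    u_slotd = np.zeros(U, dtype=int)
    u_sub[o_unit] = sv
    u_slotd[o_unit] = slotd_map[hv, iv]

    keep = slice(0, 0) if prior_only else slice(None)
    post = Posterior(
        subjects=subjects,
        horizons=[int(h) for h in horizons],
        infos=infos,
        hyper=hyper,
        variants=flags,
        sigma_is_sd=sigma_is_sd,
        include_det=include_det,
        include_ran=include_ran,
        fixed_hypers=dict(fixed_hypers) if fixed_hypers else None,
        o_dR=rows["delta_R"].to_numpy(dtype=float)[keep],
        o_dI=dI[keep],
        o_sgn=np.where(rows["chose_right"].to_numpy(dtype=bool), 1.0, -1.0)[keep],
        o_sub=sv[keep],
        o_unit=o_unit[keep],
        o_slotA=hv[keep],
        o_slotd=slotd_map[hv, iv][keep],
        o_slotr=slotr_map[hv, iv][keep],
        u_sub=u_sub,
        u_slotd=u_slotd,
        nA=H,
        nd=nd_slots,
        nr=nr_slots,
        slotA_labels=[(h, None) for h in range(H)],
        slotd_labels=slotd_labels,
        slotr_labels=slotr_labels,
    )
    return post


def model_variants(rows: pd.DataFrame, flags, **kwargs) -> Posterior:
    """Convenience wrapper: :func:`build_posterior` with a variant flag set."""
    return build_posterior(rows, variants=flags, **kwargs)


def pair_log_likelihood(
    params: SubjectParams, n_det: float, pair_rows: pd.DataFrame
) -> float:
    """Log-likelihood of one pair's observed first free choices.

    The same frozen-noise value enters both games of the pair.  With
    ``sigma_ran == 0`` an observed choice against the sign of the drive has
    probability zero and the function returns ``-inf`` (not an exception).
    """
    drive = (
        pair_rows["delta_R"].to_numpy(dtype=float)
        + params.A * pair_rows["delta_I"].to_numpy(dtype=float)
        + params.b
        + n_det
    )
    sgn = np.where(pair_rows["chose_right"].to_numpy(dtype=bool), 1.0, -1.0)
    if params.sigma_ran == 0:
        z = sgn * drive
        ll = np.where(z > 0, 0.0, np.where(z == 0, np.log(0.5), -np.inf))
        return float(ll.sum())
    return float(log_expit(sgn * drive / params.sigma_ran).sum())


def marginal_pair_likelihood(
    params: SubjectParams, pair_rows: pd.DataFrame, n_quad: int = 96
) -> float:
    """Pair likelihood with the frozen noise integrated out by quadrature.

    Substituting n_det = sigma_det * logit(u) turns the logistic prior into
    Uniform(0, 1); Gauss-Legendre nodes on (0, 1) then do the integral.  A
    cross-check utility: the MCMC samples the latent explicitly instead.
    """
    if params.sigma_det == 0:
        return float(np.exp(pair_log_likelihood(params, 0.0, pair_rows)))
    x, w = np.polynomial.legendre.leggauss(n_quad)
    u = 0.5 * (x + 1.0)
    wu = 0.5 * w
    nd = params.sigma_det * np.log(u / (1.0 - u))
    vals = np.array(
        [np.exp(pair_log_likelihood(params, float(n), pair_rows)) for n in nd]
    )
    return float((wu * vals).sum())
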