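"""File I/O, run configuration, and the end-to-end pipeline.

Trial tables travel as plain UTF-8 CSV with the exact header
``subject_id,game_id,pair_id,repeat_index,horizon,info_condition,
trial_index,is_forced,side,reward`` (pair_id empty for unpaired games,
info_condition encoded "13"/"22", is_forced 0/1), optionally followed by the
documented extras ``analysis``, ``mean_left``, ``mean_right``.

A single master seed drives everything; each pipeline stage derives its own
child stream from (master, stage index), so stages can be rerun
independently and two runs with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import DataError
from . import stats as mf
from .hier import HyperPriorConfig, build_posterior
from .mcmc import MCMCConfig, run_mcmc
from .diagnostics import convergence_check
from .summaries import derived_summaries
from .task import OPTIONAL_TRIAL_COLUMNS, TRIAL_COLUMNS, TaskConfig, first_free_choices, validate_trials
from .validation import posterior_predictive_check, simulate_cohort, make_grid_truths, RecoveryDesign

__all__ = [
    "read_trials",
    "write_trials",
    "read_config",
    "RunConfig",
    "child_seed",
    "run_pipeline",
]

log = logging.getLogger("dualnoise")

#: Fixed stage indices of the child-seed derivation scheme.
STAGES = {"simulate": 0, "analyze": 1, "fit": 2, "ppc": 3, "recover": 4, "controls": 5}


def child_seed(master: int, stage: str) -> np.random.SeedSequence:
    """Derive a stage-specific seed stream from the master seed."""
    return np.random.SeedSequence([int(master) & 0x7FFFFFFF, STAGES[stage]])


def read_trials(path) -> pd.DataFrame:
    """Read and invariant-check a trial-table CSV; row order is preserved."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    df = pd.read_csv(
        path, dtype={"pair_id": str, "info_condition": str, "subject_id": str},
        keep_default_na=False, na_values=[],
    )
    expected = TRIAL_COLUMNS
    got = list(df.columns)
    if got[: len(expected)] != expected:
        raise DataError(
            f"header mismatch: expected {expected} (optionally followed by "
            f"{OPTIONAL_TRIAL_COLUMNS}), got {got}"
        )
    extra = set(got[len(expected):]) - set(OPTIONAL_TRIAL_COLUMNS)
    if extra:
        raise DataError(f"unknown trailing columns: {sorted(extra)}")
    for col in ("horizon", "trial_index", "is_forced", "reward", "repeat_index"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise DataError(f"non-numeric value in column {col}: {exc}") from None
    return validate_trials(df)


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as CSV in the canonical column order."""
    cols = TRIAL_COLUMNS + [c for c in OPTIONAL_TRIAL_COLUMNS if c in trials.columns]
    trials[cols].to_csv(path, index=False)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run."""

    task: TaskConfig = field(default_factory=TaskConfig)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    variants: tuple[str, ...] = ()
    sigma_is_sd: bool = False
    narrow_hyperpriors: bool = False
    n_subjects: int = 8
    sigma_grid: tuple[float, float] = (0.0, 10.0)
    n_bins: int = 4
    exclusions: bool = True
    ppc_replicates: int = 20
    out_dir: str = "dualnoise_out"
    seed: int = 0
    log_level: str = "INFO"


def read_config(path) -> RunConfig:
    """Load a RunConfig from a flat TOML file (tables ``task`` and ``mcmc``
    mirror TaskConfig / MCMCConfig fields; everything else is top-level)."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    task = TaskConfig(**raw.pop("task", {}))
    mcmc = MCMCConfig(**raw.pop("mcmc", {}))
    if "variants" in raw:
        raw["variants"] = tuple(raw["variants"])
    if "sigma_grid" in raw:
        raw["sigma_grid"] = tuple(raw["sigma_grid"])
    return RunConfig(task=task, mcmc=mcmc, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """simulate -> exclude -> model-free -> fit -> derived -> PPC.

    Writes each stage's outputs under ``config.out_dir`` plus a manifest with
    seeds and artifact hashes; rerunning with the same config and seed
    reproduces every file byte-for-byte.  Returns the manifest dict.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    if config.mcmc.samples < 5000 or config.mcmc.chains < 10:
        log.info(
            "MCMC settings below the 10x5000 reference configuration: "
            "chains=%d samples=%d", config.mcmc.chains, config.mcmc.samples,
        )

    # --- simulate a cohort under grid truths (synthetic study data) -------
    rng = np.random.default_rng(child_seed(config.seed, "simulate"))
    design = RecoveryDesign(
        n_subjects=config.n_subjects,
        sigma_grid=tuple(config.sigma_grid),
        task=config.task,
        seed=config.seed,
    )
    truths = make_grid_truths(design, rng)
    trials, games = simulate_cohort(truths, config.task, config.seed)
    write_trials(trials, out / "trials.csv")
    truths.to_csv(out / "true_parameters.csv", index=False)
    artifacts["trials.csv"] = _sha256(out / "trials.csv")
    artifacts["true_parameters.csv"] = _sha256(out / "true_parameters.csv")

    # --- exclusion --------------------------------------------------------
    excl = mf.exclude_subjects(trials)
    excl.to_csv(out / "exclusions.csv", index=False)
    artifacts["exclusions.csv"] = _sha256(out / "exclusions.csv")
    if config.exclusions:
        kept = excl.loc[excl["kept"], "subject_id"]
        trials = trials[trials["subject_id"].isin(kept)]
        if not len(trials):
            raise DataError("all subjects excluded")

    # --- model-free -------------------------------------------------------
    rows = first_free_choices(trials)
    stats_table = mf.subject_stats(rows, n_bins=config.n_bins)
    stats_table.to_csv(out / "model_free.csv", index=False)
    artifacts["model_free.csv"] = _sha256(out / "model_free.csv")

    # --- hierarchical fit -------------------------------------------------
    hyper = HyperPriorConfig.narrow() if config.narrow_hyperpriors else None
    post = build_posterior(
        rows, hyper=hyper, variants=config.variants, sigma_is_sd=config.sigma_is_sd
    )
    draws = run_mcmc(post, config.mcmc)
    draws.to_frame().to_csv(out / "samples.csv", index=False)
    artifacts["samples.csv"] = _sha256(out / "samples.csv")
    conv = convergence_check(draws)
    conv.table.to_csv(out / "diagnostics.csv", index=False)
    artifacts["diagnostics.csv"] = _sha256(out / "diagnostics.csv")

    # --- derived summaries ------------------------------------------------
    if post.include_det and post.include_ran:
        derived = derived_summaries(draws)
        derived.summary().to_csv(out / "derived.csv", index=False)
        artifacts["derived.csv"] = _sha256(out / "derived.csv")

    # --- posterior predictive check --------------------------------------
    ppc = posterior_predictive_check(
        draws, games, rows, n_rep=config.ppc_replicates,
        seed=config.seed, task=config.task,
    )
    ppc.bands.merge(ppc.observed, on=["statistic", "horizon", "info"]).rename(
        columns={"value": "observed"}
    ).to_csv(out / "ppc.csv", index=False)
    artifacts["ppc.csv"] = _sha256(out / "ppc.csv")

    manifest = {
        "seed": config.seed,
        "config": {
            "task": asdict(config.task),
            "mcmc": asdict(config.mcmc),
            **{
                f.name: getattr(config, f.name)
                for f in fields(config)
                if f.name not in ("task", "mcmc")
            },
        },
        "converged": bool(conv.passed),
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
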