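"""End-to-end pipeline: simulate -> NCA -> statistics -> report bundle.

Given a :class:`~xanpk.io.RunConfig`, writes to the output directory:

* ``cohort.csv``        — the generated subjects and their parameters
* ``profiles.csv``      — one row per saliva sample, all conditions
* ``nca_subjects.csv``  — per-subject kinetic descriptors
* ``nca_summary.csv``   — cohort summary in the kinetics-table shape
* ``associations.csv``  — the three-test FDR family
* ``contrasts.csv``     — per-grid-point paired caffeine-vs-placebo tests
* ``manifest.json``     — config echo + package version + seed + design
  constants; re-running from the manifest reproduces every file.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import PopulationConfig, generate_cohort
from .design import build_schedule
from .io import RunConfig, write_cohort, write_profiles
from .nca import nca_table, summarize_nca
from .simulate import simulate_study
from .stats import association_table, pointwise_contrast

__all__ = ["run_pipeline"]

log = logging.getLogger("xanpk")


class PipelineError(RuntimeError):
    """Wraps a stage failure with the stage name."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # annotate with the failing stage
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def _population_config(cfg: RunConfig) -> PopulationConfig:
    return PopulationConfig(
        weight_mean_kg=cfg.weight_mean_kg,
        weight_sd_kg=cfg.weight_sd_kg,
        intake_range_mg_day=cfg.intake_range_mg_day,
        half_life_parent_h=cfg.half_life_parent_h,
        half_life_metab_h=cfg.half_life_metab_h,
        beta_parent=cfg.beta_parent,
        beta_metab=cfg.beta_metab,
        ka=cfg.ka,
        fm=cfg.fm,
        v_parent=cfg.v_parent,
        v_metab=cfg.v_metab,
        cv_ke=cfg.cv_ke,
        cv_km=cfg.cv_km,
        cv_v=cfg.cv_v,
        lloq_parent=cfg.lloq_parent,
        lloq_metab=cfg.lloq_metab,
    )


@_stage("simulate")
def _simulate(cfg: RunConfig):
    cohort = generate_cohort(cfg.n_subjects, cfg.seed, _population_config(cfg))
    profiles = simulate_study(
        cohort,
        conditions=cfg.conditions,
        noise_cv=cfg.noise_cv,
        seed=cfg.seed,
        n_days=cfg.n_days,
        dose_mg=cfg.dose_mg,
        dose_offsets_h=cfg.dose_offsets_h,
        wake_interval_h=cfg.wake_interval_h,
    )
    log.info(
        "simulated %d subjects x %d conditions -> %d samples (%d censored)",
        len(cohort), len(cfg.conditions), len(profiles), int(profiles["censored"].sum()),
    )
    return cohort, profiles


@_stage("nca")
def _nca(cfg: RunConfig, profiles: pd.DataFrame):
    table = nca_table(profiles, interpolation=cfg.interpolation)
    summary = summarize_nca(table)
    n_undef = int(table["flags"].astype(bool).sum())
    log.info("NCA: %d subject x analyte rows, %d with undefined descriptors",
             len(table), n_undef)
    return table, summary


@_stage("stats")
def _stats(cfg: RunConfig, cohort, table: pd.DataFrame, profiles: pd.DataFrame):
    cohort_df = pd.DataFrame(
        dict(
            subject_id=[s.id for s in cohort],
            habitual_mg_kg_day=[s.habitual_mg_kg_day for s in cohort],
        )
    )
    associations = association_table(cohort_df, table, fdr_mode=cfg.fdr_mode)
    log.info("associations: %d tests in one FDR family", len(associations))

    contrasts = pd.DataFrame()
    if {"caffeine", "placebo"} <= set(cfg.conditions):
        frames = []
        for analyte in ("caffeine", "paraxanthine"):
            sub = profiles[profiles["analyte"] == analyte]
            pa = sub[sub["condition"] == "caffeine"].pivot(
                index="subject_id", columns="time_h", values="conc_ug_ml"
            )
            pb = sub[sub["condition"] == "placebo"].pivot(
                index="subject_id", columns="time_h", values="conc_ug_ml"
            )
            pb = pb.loc[pa.index, pa.columns]
            labels = (
                sub[sub["condition"] == "caffeine"]
                .drop_duplicates("time_h")
                .sort_values("time_h")["time_after_last_dose_h"]
                .to_numpy()
            )
            res = pointwise_contrast(pa.to_numpy(), pb.to_numpy(), labels)
            frames.append(
                pd.DataFrame([r.__dict__ for r in res]).assign(analyte=analyte)
            )
        contrasts = pd.concat(frames, ignore_index=True)
        log.info("contrasts: %d grid points x 2 analytes", len(contrasts) // 2)
    return associations, contrasts


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full chain and write the report bundle; returns the manifest."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort, profiles = _simulate(config)
    table, summary = _nca(config, profiles)
    associations, contrasts = _stats(config, cohort, table, profiles)

    write_cohort(cohort, out / "cohort.csv")
    write_profiles(profiles, out / "profiles.csv")
    table.to_csv(out / "nca_subjects.csv", index=False)
    summary.to_csv(out / "nca_summary.csv", index=False)
    associations.to_csv(out / "associations.csv", index=False)
    contrasts.to_csv(out / "contrasts.csv", index=False)

    caffeine_day10_dose = build_schedule(
        "caffeine", n_days=config.n_days, dose_mg=config.dose_mg,
        dose_offsets_h=config.dose_offsets_h, wake_interval_h=config.wake_interval_h,
    ).daily_active_dose(config.n_days - 1, config.wake_interval_h)

    manifest = {
        "package": "xanpk",
        "version": __version__,
        "seed": config.seed,
        "caffeine_day10_total_dose_mg": float(caffeine_day10_dose),
        "n_samples": int(len(profiles)),
        "n_censored": int(profiles["censored"].sum()),
        "config": config.to_dict(),
        "outputs": [
            "cohort.csv", "profiles.csv", "nca_subjects.csv",
            "nca_summary.csv", "associations.csv", "contrasts.csv",
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("wrote report bundle to %s", out)
    return manifest
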