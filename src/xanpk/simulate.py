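"""Concentration profiles: multi-dose superposition, assay noise, censoring.

Because the kinetics are linear, the concentration under any dosing
schedule is the sum of time-shifted single-dose curves (superposition).
Assay error is multiplicative log-normal with a configurable CV, and
values below the LLOQ are recorded as 0 with a censored flag, mirroring
how a chromatography assay reports sub-calibrator samples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import Subject
from .design import DosingSchedule, SamplingGrid, build_schedule, default_grid
from .model import metabolite_conc, parent_conc

__all__ = [
    "ConcentrationProfile",
    "simulate_profiles",
    "apply_noise",
    "simulate_study",
]

ANALYTES = ("caffeine", "paraxanthine")


@dataclass(frozen=True)
class ConcentrationProfile:
    """Analyte concentration vs time on a sampling grid.

    ``censored`` marks samples below the LLOQ; their concentration is
    recorded as 0.  ``times`` are hours since study start.
    """

    analyte: str
    times: np.ndarray
    conc: np.ndarray
    censored: np.ndarray
    subject_id: str | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        conc = np.asarray(self.conc, dtype=float)
        censored = np.asarray(self.censored, dtype=bool)
        if not (times.shape == conc.shape == censored.shape):
            raise ValueError("times, conc and censored must have matching shapes")
        if np.any(conc < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any(conc[censored] != 0):
            raise ValueError("censored samples must carry concentration 0")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "conc", conc)
        object.__setattr__(self, "censored", censored)

    def __len__(self) -> int:
        return self.times.size


def simulate_profiles(
    schedule: DosingSchedule,
    subject: Subject,
    grid: SamplingGrid,
) -> tuple[ConcentrationProfile, ConcentrationProfile]:
    """Noise-free caffeine and paraxanthine profiles on ``grid``.

    Each grid concentration is the superposition over active dose events of
    the single-dose closed forms evaluated at (t - event time).
    """
    t = grid.times
    ca = np.zeros_like(t)
    px = np.zeros_like(t)
    for ev in schedule.active_events:
        ca += parent_conc(t - ev.time_h, ev.dose_mg, subject.params)
        px += metabolite_conc(t - ev.time_h, ev.dose_mg, subject.params)
    mk = lambda analyte, c: ConcentrationProfile(
        analyte=analyte,
        times=t.copy(),
        conc=c,
        censored=np.zeros_like(t, dtype=bool),
        subject_id=subject.id,
        condition=schedule.condition,
    )
    return mk("caffeine", ca), mk("paraxanthine", px)


def apply_noise(
    profile: ConcentrationProfile,
    cv: float,
    lloq: float,
    seed: int | np.random.Generator = 0,
) -> ConcentrationProfile:
    """Multiplicative log-normal assay error plus LLOQ censoring.

    The noise multiplier is mean-1 log-normal, ``exp(sigma*Z - sigma^2/2)``
    with ``sigma^2 = ln(1 + cv^2)``, so the error is unbiased on the
    concentration scale with coefficient of variation ``cv``.  Values below
    ``lloq`` are set to 0 and flagged censored.  ``cv=0`` with nothing below
    the LLOQ is the identity.
    """
    if cv < 0:
        raise ValueError("cv must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    conc = profile.conc.copy()
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv * cv))
        conc = conc * np.exp(sigma * rng.standard_normal(conc.shape) - 0.5 * sigma**2)
    censored = conc < lloq
    conc = np.where(censored, 0.0, conc)
    return replace(profile, conc=conc, censored=censored)


def simulate_study(
    cohort: list[Subject],
    conditions: tuple[str, ...] = ("caffeine", "deprivation", "placebo"),
    noise_cv: float = 0.0,
    seed: int = 0,
    n_days: int = 10,
    dose_mg: float = 150.0,
    dose_offsets_h: tuple[float, ...] = (0.75, 4.0, 8.0),
    wake_interval_h: float = 24.0,
) -> pd.DataFrame:
    """Simulate the full study; returns one tidy row per saliva sample.

    Columns: subject_id, condition, analyte, time_h,
    time_after_last_dose_h, conc_ug_ml, censored.  Noise streams are
    derived per (subject, condition) from the master seed, so the output
    is reproducible and insensitive to condition ordering.
    """
    rows: list[pd.DataFrame] = []
    root = np.random.SeedSequence(seed)
    cond_index = {c: i for i, c in enumerate(("caffeine", "deprivation", "placebo"))}
    for si, subject in enumerate(cohort):
        for condition in conditions:
            schedule = build_schedule(
                condition, n_days=n_days, dose_mg=dose_mg,
                dose_offsets_h=dose_offsets_h, wake_interval_h=wake_interval_h,
            )
            grid = default_grid(
                schedule, n_days=n_days, dose_offsets_h=dose_offsets_h,
                wake_interval_h=wake_interval_h,
            )
            ca, px = simulate_profiles(schedule, subject, grid)
            # censoring applies even when noise_cv == 0
            ss = np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(si, cond_index[condition])
            )
            rng_ca, rng_px = (np.random.default_rng(s) for s in ss.spawn(2))
            ca = apply_noise(ca, noise_cv, subject.params.lloq_parent, rng_ca)
            px = apply_noise(px, noise_cv, subject.params.lloq_metab, rng_px)
            for prof in (ca, px):
                rows.append(
                    pd.DataFrame(
                        {
                            "subject_id": subject.id,
                            "condition": condition,
                            "analyte": prof.analyte,
                            "time_h": prof.times,
                            "time_after_last_dose_h": grid.labels,
                            "conc_ug_ml": prof.conc,
                            "censored": prof.censored.astype(int),
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)
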