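"""Non-compartmental kinetic descriptors for concentration profiles.

The descriptors follow the study's operational definitions rather than
textbook lambda-z conventions:

* Cmax / Tmax — maximal uncensored level strictly after the last dose and
  its latency from that dose; ties broken by the earlier sample.  Tmax is
  grid-censored: it can never be smaller than the first post-dose sample
  latency (1.75 h on the default grid).
* half-life — time from the peak sample to the point where the profile
  crosses half the maximum (C50), interpolated log-linearly between the
  bracketing samples (exact for exponential decline); undefined (NaN) when
  the grid never crosses C50.
* K_el — minus the OLS slope of ln(concentration) on time over all
  uncensored positive samples strictly after Tmax (>= 3 required).
* AUC — plain trapezoidal rule over a time window; censored samples enter
  as 0.
* overnight residual — the concentration at the pre-first-dose baseline
  sample of the final day (~17 h after the previous day's last capsule).

Undefined descriptors are NaN values with a reason flag, not exceptions;
summaries drop them pairwise and report the exclusion counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import ConcentrationProfile

__all__ = [
    "NCAResult",
    "UndefinedResultError",
    "peak",
    "half_life_c50",
    "kel_loglinear",
    "auc_trapezoid",
    "overnight_residual",
    "disproportionality",
    "nca_table",
    "summarize_nca",
]


class UndefinedResultError(ValueError):
    """A descriptor whose preconditions make it uncomputable (hard error)."""


@dataclass(frozen=True)
class NCAResult:
    """The kinetic descriptors for one subject x analyte x condition."""

    subject_id: str | None
    condition: str | None
    analyte: str
    cmax: float
    tmax: float
    half_life: float  # NaN when undefined
    kel: float  # NaN when undefined
    auc: float
    auc_window: str  # "AUCc" or "AUCw"
    overnight_residual: float
    flags: tuple[str, ...] = field(default_factory=tuple)


def _uncensored(profile: ConcentrationProfile) -> tuple[np.ndarray, np.ndarray]:
    keep = ~profile.censored
    return profile.times[keep], profile.conc[keep]


def peak(profile: ConcentrationProfile, last_dose_time: float) -> tuple[float, float]:
    """(cmax, tmax): maximal uncensored level after the last dose.

    ``tmax`` is hours after ``last_dose_time``; ties go to the earliest
    sample.  Raises :class:`UndefinedResultError` when no uncensored
    post-dose sample exists.
    """
    t, c = _uncensored(profile)
    post = t > last_dose_time
    if not post.any():
        raise UndefinedResultError(
            f"no uncensored sample after the last dose at t={last_dose_time} h"
        )
    t, c = t[post], c[post]
    i = int(np.argmax(c))  # argmax returns the first maximum -> earliest tie
    return float(c[i]), float(t[i] - last_dose_time)


def half_life_c50(
    profile: ConcentrationProfile,
    last_dose_time: float,
    interpolation: str = "log",
) -> float:
    """Half-life as time from the peak to the C50 (half-of-Cmax) crossing.

    Scans consecutive uncensored samples from the peak onward for the first
    bracketing pair C_i >= Cmax/2 >= C_{i+1} and interpolates the crossing
    time log-linearly (``interpolation="linear"`` switches to straight-line
    interpolation for sensitivity analyses).  Returns NaN when the profile
    never reaches C50 within the grid.
    """
    if interpolation not in ("log", "linear"):
        raise ValueError(f"interpolation must be 'log' or 'linear', got {interpolation!r}")
    cmax, tmax = peak(profile, last_dose_time)
    target = cmax / 2.0
    t, c = _uncensored(profile)
    post = t > last_dose_time
    t, c = t[post], c[post]
    start = int(np.argmax(c))
    t_peak = t[start]
    for i in range(start, len(t) - 1):
        if c[i] >= target >= c[i + 1] and c[i] > c[i + 1]:
            if interpolation == "log" and c[i + 1] > 0:
                frac = (math.log(c[i]) - math.log(target)) / (
                    math.log(c[i]) - math.log(c[i + 1])
                )
            else:
                frac = (c[i] - target) / (c[i] - c[i + 1])
            t_cross = t[i] + frac * (t[i + 1] - t[i])
            return float(t_cross - t_peak)
    return float("nan")


def kel_loglinear(profile: ConcentrationProfile, last_dose_time: float) -> float:
    """Elimination rate: minus the OLS log-linear slope after the peak.

    Uses every uncensored sample with positive concentration strictly after
    Tmax; returns NaN when fewer than 3 such samples remain.
    """
    _, tmax = peak(profile, last_dose_time)
    t, c = _uncensored(profile)
    sel = (t > last_dose_time + tmax) & (c > 0)
    t, c = t[sel], c[sel]
    if t.size < 3:
        return float("nan")
    slope = np.polyfit(t, np.log(c), 1)[0]
    return float(-slope)


def auc_trapezoid(
    profile: ConcentrationProfile, t_start: float, t_end: float
) -> float:
    """Trapezoidal AUC (ug*h/ml) over [t_start, t_end]; censored enter as 0."""
    sel = (profile.times >= t_start - 1e-9) & (profile.times <= t_end + 1e-9)
    t = profile.times[sel]
    c = np.where(profile.censored[sel], 0.0, profile.conc[sel])
    if t.size < 2:
        raise UndefinedResultError(
            f"AUC needs >= 2 samples in [{t_start}, {t_end}] h, found {t.size}"
        )
    return float(np.trapezoid(c, t))


def overnight_residual(profile: ConcentrationProfile, pre_dose_time: float) -> float:
    """Concentration at the pre-first-dose baseline sample (censored -> 0)."""
    idx = np.nonzero(np.isclose(profile.times, pre_dose_time, atol=1e-6))[0]
    if idx.size == 0:
        raise UndefinedResultError(
            f"no baseline sample at t={pre_dose_time} h in the profile"
        )
    i = int(idx[0])
    return 0.0 if profile.censored[i] else float(profile.conc[i])


def disproportionality(auc_px: float, auc_ca: float) -> float:
    """Metabolite/parent AUC ratio; NaN when the denominator is not positive."""
    if not auc_ca > 0:
        return float("nan")
    return float(auc_px / auc_ca)


# ---------------------------------------------------------------------------
# cohort-level tables


def _profile_from_rows(rows: pd.DataFrame, analyte: str) -> ConcentrationProfile:
    rows = rows.sort_values("time_h")
    return ConcentrationProfile(
        analyte=analyte,
        times=rows["time_h"].to_numpy(float),
        conc=rows["conc_ug_ml"].to_numpy(float),
        censored=rows["censored"].to_numpy(bool),
        subject_id=str(rows["subject_id"].iloc[0]),
        condition=str(rows["condition"].iloc[0]),
    )


def nca_table(profiles: pd.DataFrame, interpolation: str = "log") -> pd.DataFrame:
    """Per-subject NCA descriptors from a tidy profiles table.

    Descriptors (Cmax, Tmax, half-life, Kel, residual, AUCc) come from the
    caffeine condition; AUCw is the deprivation-window AUC when that
    condition is present.  Last-dose reference times are taken from the
    ``time_after_last_dose_h`` column, so externally supplied tables work
    as long as they carry that column.
    """
    out: list[dict] = []
    caffeine = profiles[profiles["condition"] == "caffeine"]
    deprivation = profiles[profiles["condition"] == "deprivation"]
    for (sid, analyte), grp in caffeine.groupby(["subject_id", "analyte"], sort=True):
        prof = _profile_from_rows(grp, analyte)
        # recover the absolute last-dose time from the reporting labels
        last_dose = float(
            (grp["time_h"] - grp["time_after_last_dose_h"]).iloc[0]
        )
        flags: list[str] = []
        try:
            cmax, tmax = peak(prof, last_dose)
        except UndefinedResultError:
            cmax = tmax = float("nan")
            flags.append("no_post_dose_samples")
        hl = half_life_c50(prof, last_dose, interpolation) if np.isfinite(cmax) else float("nan")
        if not np.isfinite(hl):
            flags.append("half_life_undefined")
        kel = kel_loglinear(prof, last_dose) if np.isfinite(cmax) else float("nan")
        if not np.isfinite(kel):
            flags.append("kel_undefined")
        auc_c = auc_trapezoid(prof, prof.times[0], prof.times[-1])
        residual = overnight_residual(prof, prof.times[0])

        auc_w = float("nan")
        dep = deprivation[
            (deprivation["subject_id"] == sid) & (deprivation["analyte"] == analyte)
        ]
        if len(dep) >= 2:
            dprof = _profile_from_rows(dep, analyte)
            auc_w = auc_trapezoid(dprof, dprof.times[0], dprof.times[-1])

        out.append(
            dict(
                subject_id=sid,
                condition="caffeine",
                analyte=analyte,
                cmax=cmax,
                tmax=tmax,
                half_life=hl,
                kel=kel,
                auc_c=auc_c,
                auc_w=auc_w,
                residual=residual,
                flags=";".join(flags),
            )
        )
    if not out:
        raise UndefinedResultError("no caffeine-condition profiles to analyse")
    table = pd.DataFrame(out)
    ca = table[table["analyte"] == "caffeine"].set_index("subject_id")
    px = table[table["analyte"] == "paraxanthine"].set_index("subject_id")
    shared = ca.index.intersection(px.index)
    ratio = pd.Series(
        [disproportionality(px.loc[s, "auc_c"], ca.loc[s, "auc_c"]) for s in shared],
        index=shared,
        name="auc_ratio_px_ca",
    )
    table = table.merge(
        ratio.rename_axis("subject_id").reset_index(), on="subject_id", how="left"
    )
    return table


_MEDIAN_METRICS = ("tmax", "half_life")
_MEAN_METRICS = ("kel", "cmax", "residual", "auc_c", "auc_w")
_METRIC_COLUMNS = {  # summary row order mirrors the study's kinetics table
    "tmax": "peak_time_h",
    "half_life": "half_life_h",
    "kel": "kel_per_h",
    "cmax": "peak_level_ug_ml",
    "residual": "overnight_residual_ug_ml",
    "auc_c": "auc_c_ug_h_ml",
    "auc_w": "auc_w_ug_h_ml",
}


def summarize_nca(table: pd.DataFrame) -> pd.DataFrame:
    """Cohort summary in the shape of the study's kinetics table.

    Peak time and half-life are summarised as median (IQR); the remaining
    descriptors as mean +/- SD (max-min), SD with the n-1 denominator.
    Undefined (NaN) values are excluded pairwise and counted in
    ``n_excluded``.
    """
    if table.empty:
        raise UndefinedResultError("cannot summarise an empty NCA table")
    rows = []
    for analyte, grp in table.groupby("analyte", sort=True):
        for metric, colname in _METRIC_COLUMNS.items():
            vals = grp[metric].to_numpy(float)
            ok = vals[np.isfinite(vals)]
            row = dict(
                analyte=analyte,
                metric=colname,
                n_used=ok.size,
                n_excluded=vals.size - ok.size,
            )
            if ok.size:
                if metric in _MEDIAN_METRICS:
                    row.update(
                        median=float(np.median(ok)),
                        q1=float(np.percentile(ok, 25)),
                        q3=float(np.percentile(ok, 75)),
                    )
                else:
                    row.update(
                        mean=float(np.mean(ok)),
                        sd=float(np.std(ok, ddof=1)) if ok.size > 1 else 0.0,
                        min=float(np.min(ok)),
                        max=float(np.max(ok)),
                    )
            rows.append(row)
    return pd.DataFrame(rows)
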