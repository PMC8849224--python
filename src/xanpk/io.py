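"""CSV interchange and run configuration.

CSV is the single interchange format: the data are small and auditable.
Profiles tables carry one row per saliva sample with the documented header;
concentrations are stored in ug/ml, with ng/ml accepted on input through an
explicit flag or a ``units`` column.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "PROFILE_COLUMNS",
    "COHORT_COLUMNS",
    "ValidationError",
    "read_profiles",
    "write_profiles",
    "read_cohort",
    "write_cohort",
    "RunConfig",
]

PROFILE_COLUMNS = [
    "subject_id",
    "condition",
    "analyte",
    "time_h",
    "time_after_last_dose_h",
    "conc_ug_ml",
    "censored",
]

COHORT_COLUMNS = [
    "subject_id",
    "weight_kg",
    "habitual_mg_day",
    "habitual_mg_kg_day",
    "ka",
    "ke",
    "km",
    "fm",
    "v_parent",
    "v_metab",
]


class ValidationError(ValueError):
    """Input table violates the interchange contract; names the first bad row."""


def write_profiles(profiles: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in PROFILE_COLUMNS if c not in profiles.columns]
    if missing:
        raise ValidationError(f"profiles table is missing columns {missing}")
    profiles[PROFILE_COLUMNS].to_csv(path, index=False)


def read_profiles(path: str | Path, units: str = "ug_ml") -> pd.DataFrame:
    """Read a profiles CSV, validating the interchange contract.

    ``units`` may be ``"ug_ml"`` (default) or ``"ng_ml"``; alternatively a
    per-row ``units`` column with those labels is honoured.  Values are
    always stored as ug/ml.  Negative concentrations and duplicate
    (subject, condition, analyte, time) keys are rejected with a message
    naming the offending row.
    """
    if units not in ("ug_ml", "ng_ml"):
        raise ValidationError(f"units must be 'ug_ml' or 'ng_ml', got {units!r}")
    df = pd.read_csv(path)
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    if "units" in df.columns:
        bad = ~df["units"].isin(["ug_ml", "ng_ml"])
        if bad.any():
            raise ValidationError(
                f"{path}: row {int(df.index[bad][0])}: unknown units "
                f"{df.loc[bad, 'units'].iloc[0]!r}"
            )
        scale = df["units"].map({"ug_ml": 1.0, "ng_ml": 1e-3})
        df["conc_ug_ml"] = df["conc_ug_ml"] * scale
        df = df.drop(columns=["units"])
    elif units == "ng_ml":
        df["conc_ug_ml"] = df["conc_ug_ml"] * 1e-3
    neg = df["conc_ug_ml"] < 0
    if neg.any():
        i = int(df.index[neg][0])
        raise ValidationError(
            f"{path}: row {i}: negative concentration {df.loc[i, 'conc_ug_ml']!r}"
        )
    key = ["subject_id", "condition", "analyte", "time_h"]
    dup = df.duplicated(subset=key)
    if dup.any():
        i = int(df.index[dup][0])
        raise ValidationError(
            f"{path}: row {i}: duplicate sample key "
            f"{tuple(df.loc[i, key])}"
        )
    df["censored"] = df["censored"].astype(int)
    return df[PROFILE_COLUMNS]


def write_cohort(cohort, path: str | Path) -> None:
    """Write a cohort (list of Subject or a DataFrame) to CSV."""
    if not isinstance(cohort, pd.DataFrame):
        cohort = pd.DataFrame(
            [
                dict(
                    subject_id=s.id,
                    weight_kg=s.weight_kg,
                    habitual_mg_day=s.habitual_mg_day,
                    habitual_mg_kg_day=s.habitual_mg_kg_day,
                    ka=s.params.ka,
                    ke=s.params.ke,
                    km=s.params.km,
                    fm=s.params.fm,
                    v_parent=s.params.v_parent,
                    v_metab=s.params.v_metab,
                )
                for s in cohort
            ]
        )
    cohort[COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    return df[COHORT_COLUMNS]


@dataclass
class RunConfig:
    """Everything a pipeline run needs; defaults reproduce the study design.

    150 mg x 3/day x 10 days, N=20, the 11-sample day-10 grid, LLOQs of
    0.04 (caffeine) and 0.02 (paraxanthine) ug/ml, and the printed
    covariate slopes.
    """

    seed: int = 0
    n_subjects: int = 20
    n_days: int = 10
    dose_mg: float = 150.0
    dose_offsets_h: tuple[float, ...] = (0.75, 4.0, 8.0)
    wake_interval_h: float = 24.0
    conditions: tuple[str, ...] = ("caffeine", "deprivation", "placebo")
    noise_cv: float = 0.1
    # population
    weight_mean_kg: float = 76.2
    weight_sd_kg: float = 8.7
    intake_range_mg_day: tuple[float, float] = (300.0, 600.0)
    half_life_parent_h: float = 4.33
    half_life_metab_h: float = 7.79
    beta_parent: float = -0.11
    beta_metab: float = -0.14
    ka: float = 3.0
    fm: float = 0.84
    v_parent: float = 43.1
    v_metab: float = 19.6
    cv_ke: float = 0.3
    cv_km: float = 0.3
    cv_v: float = 0.3
    lloq_parent: float = 0.04
    lloq_metab: float = 0.02
    # analysis
    interpolation: str = "log"  # C50 crossing: "log" or "linear"
    fdr_mode: str = "standard"  # or "rank_scaled"
    out_dir: str = "xanpk_run"

    def __post_init__(self) -> None:
        self.dose_offsets_h = tuple(float(x) for x in self.dose_offsets_h)
        self.conditions = tuple(self.conditions)
        self.intake_range_mg_day = tuple(float(x) for x in self.intake_range_mg_day)
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be non-negative")
        if self.interpolation not in ("log", "linear"):
            raise ValidationError("interpolation must be 'log' or 'linear'")
        if self.fdr_mode not in ("standard", "rank_scaled"):
            raise ValidationError("fdr_mode must be 'standard' or 'rank_scaled'")
        unknown = set(self.conditions) - {"caffeine", "deprivation", "placebo"}
        if unknown:
            raise ValidationError(f"unknown conditions {sorted(unknown)}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d
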