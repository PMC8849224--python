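"""Inter-individual association statistics and condition contrasts.

Associations between habitual intake (mg/kg/day) and kinetic descriptors
are ordinary least-squares regressions with two-sided t-tests; the family
of tests is corrected for the false discovery rate.  Two FDR variants are
exposed: the standard Benjamini–Hochberg step-up adjustment and a
``rank_scaled`` variant (p*m/rank without the step-up minimum), kept
because some published q-values follow that convention.

Condition differences over the sampling grid are paired t-tests per grid
point with BH correction across the grid — a deliberately simple stand-in
for a full mixed-model interaction analysis, which is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationResult",
    "ContrastResult",
    "ols_association",
    "bh_adjust",
    "pointwise_contrast",
    "association_table",
]


class DegenerateDesignError(ValueError):
    """Raised when the regression design is unusable (constant predictor)."""


@dataclass(frozen=True)
class AssociationResult:
    predictor: str
    outcome: str
    beta: float  # slope, outcome units per predictor unit
    se: float
    p: float
    n_used: int
    n_dropped: int
    q: float = float("nan")  # filled in once the test family is adjusted


@dataclass(frozen=True)
class ContrastResult:
    index: int
    time_after_last_dose_h: float
    mean_diff: float
    t: float
    p: float
    q: float


def ols_association(
    x,
    y,
    predictor: str = "habitual_mg_kg_day",
    outcome: str = "descriptor",
) -> AssociationResult:
    """OLS slope of ``y`` on ``x`` with its standard error and t-test p.

    Pairs where either value is NaN are dropped (counted in ``n_dropped``).
    Requires >= 3 complete pairs and a non-constant predictor.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    n_dropped = int((~keep).sum())
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise DegenerateDesignError(f"need >= 3 complete pairs, have {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("predictor is constant; slope is not identifiable")
    fit = sps.linregress(x, y)
    return AssociationResult(
        predictor=predictor,
        outcome=outcome,
        beta=float(fit.slope),
        se=float(fit.stderr),
        p=float(fit.pvalue),
        n_used=int(x.size),
        n_dropped=n_dropped,
    )


def bh_adjust(pvals, mode: str = "standard") -> np.ndarray:
    """False-discovery-rate adjusted q-values.

    ``standard`` is the Benjamini–Hochberg step-up adjustment
    (q_(i) = min_{j >= i} p_(j) * m / j, capped at 1), which is monotone in
    p.  ``rank_scaled`` returns the raw p*m/rank values without enforcing
    monotonicity (ties share the larger rank); it can exceed the standard
    q-value for mid-ranked tests and is provided for comparability with
    reports that used that convention.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-D collection")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if mode == "standard":
        return multipletests(p, method="fdr_bh")[1]
    if mode == "rank_scaled":
        ranks = sps.rankdata(p, method="max")
        return np.minimum(p * p.size / ranks, 1.0)
    raise ValueError(f"unknown mode {mode!r}; expected 'standard' or 'rank_scaled'")


def pointwise_contrast(
    a: np.ndarray,
    b: np.ndarray,
    times=None,
    fdr_mode: str = "standard",
) -> list[ContrastResult]:
    """Paired t-tests of condition A vs B at each grid point.

    ``a`` and ``b`` are (n_subjects, n_times) arrays with rows matched by
    subject and columns by sample; q-values are BH-adjusted across the grid
    points.  All-zero differences give t = 0, p = 1 by convention (a
    degenerate paired t-test).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError(
            f"profiles must be matched (n_subjects, n_times) arrays, got {a.shape} vs {b.shape}"
        )
    n, m = a.shape
    if times is None:
        times = np.arange(m, dtype=float)
    times = np.asarray(times, dtype=float)
    if times.size != m:
        raise ValueError("times must match the grid dimension")
    diffs = a - b
    t_stats = np.empty(m)
    p_vals = np.empty(m)
    for j in range(m):
        d = diffs[:, j]
        if np.all(d == d[0]) and d[0] == 0:
            t_stats[j], p_vals[j] = 0.0, 1.0
        else:
            res = sps.ttest_rel(a[:, j], b[:, j])
            t_stats[j], p_vals[j] = float(res.statistic), float(res.pvalue)
    # a single subject (or zero-variance differences) yields NaN p-values;
    # adjust only the defined ones
    q = np.full(m, np.nan)
    ok = np.isfinite(p_vals)
    if ok.any():
        q[ok] = bh_adjust(p_vals[ok], mode=fdr_mode)
    return [
        ContrastResult(
            index=j,
            time_after_last_dose_h=float(times[j]),
            mean_diff=float(diffs[:, j].mean()),
            t=float(t_stats[j]),
            p=float(p_vals[j]),
            q=float(q[j]),
        )
        for j in range(m)
    ]


def association_table(
    cohort: pd.DataFrame,
    nca: pd.DataFrame,
    fdr_mode: str = "standard",
) -> pd.DataFrame:
    """The study's three-test association family as one adjusted table.

    Regresses caffeine half-life, paraxanthine half-life, and the
    paraxanthine/caffeine AUC ratio on habitual intake (mg/kg/day), then
    adjusts the three p-values as a single FDR family.
    """
    x = cohort.set_index("subject_id")["habitual_mg_kg_day"]
    outcomes: list[tuple[str, pd.Series]] = []
    for analyte in ("caffeine", "paraxanthine"):
        sub = nca[nca["analyte"] == analyte].set_index("subject_id")
        outcomes.append((f"half_life_{analyte}", sub["half_life"]))
    ratio = (
        nca[nca["analyte"] == "caffeine"]
        .set_index("subject_id")["auc_ratio_px_ca"]
    )
    outcomes.append(("auc_ratio_px_ca", ratio))
    rows = []
    for name, y in outcomes:
        aligned = pd.concat([x, y.rename("y")], axis=1, join="inner")
        try:
            r = ols_association(
                aligned["habitual_mg_kg_day"], aligned["y"],
                predictor="habitual_mg_kg_day", outcome=name,
            )
            rows.append(
                dict(predictor=r.predictor, outcome=r.outcome, beta=r.beta,
                     se=r.se, p=r.p, q=float("nan"), n_used=r.n_used,
                     n_dropped=r.n_dropped)
            )
        except DegenerateDesignError:
            # too few complete pairs or a constant predictor: report the
            # test as undefined rather than failing the whole family
            complete = int(aligned.notna().all(axis=1).sum())
            rows.append(
                dict(predictor="habitual_mg_kg_day", outcome=name,
                     beta=float("nan"), se=float("nan"), p=float("nan"),
                     q=float("nan"), n_used=complete,
                     n_dropped=int(len(aligned)) - complete)
            )
    table = pd.DataFrame(rows)
    ok = table["p"].notna()
    if ok.any():
        table.loc[ok, "q"] = bh_adjust(table.loc[ok, "p"].to_numpy(), mode=fdr_mode)
    return table
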