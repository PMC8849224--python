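# xanpk — salivary caffeine/paraxanthine kinetics under daily dosing

Most caffeine pharmacokinetics is described after a single dose, yet most
people dose themselves several times a day, every day.  Under such a
regimen neither caffeine nor its principal metabolite paraxanthine (formed
from ~84% of caffeine via hepatic CYP1A2, and itself an active adenosine
antagonist) is fully eliminated overnight, and the degree of carry-over
depends on each person's clearance — which in turn co-varies with their
habitual intake.

`xanpk` is a library for studying exactly this setting.  It provides, for
researchers designing or re-analysing repeated-dose caffeine studies:

1. **A seeded study simulator** — closed-form one-compartment kinetics with
   first-order absorption (`ka`), parent elimination (`ke` = K_el), and
   metabolite formation/elimination (`fm`, `km`):

   parent (Bateman):  C_p(t) = (D/V_p) · ka/(ka−ke) · (e^(−ke·t) − e^(−ka·t))

   metabolite:  C_m(t) = fm·D·ka·ke/V_m · Σ_i e^(−k_i·t) / Π_{j≠i}(k_j−k_i),
   k ∈ {ka, ke, km}

   superposed over a 10-day, 150 mg × 3/day dosing schedule in three
   within-subject conditions (caffeine, acute deprivation sampled 24–43 h
   after the last dose, placebo), sampled on an 11-point day-10 saliva grid,
   with log-normal inter-individual variability, a linear covariate effect
   of habitual intake (mg/kg/day) on the half-lives, multiplicative assay
   noise, and LLOQ censoring (0.04 / 0.02 μg/ml).

2. **Non-compartmental descriptors** as defined operationally for such
   sparse clinical grids: Cmax and grid-censored Tmax after the last dose,
   the *C50 half-life* (time from the peak to the log-linearly interpolated
   crossing of half-maximum), log-linear K_el over post-peak samples,
   trapezoidal AUC over the caffeine (AUCc) and deprivation (AUCw) windows,
   the overnight pre-dose residual, and the paraxanthine/caffeine AUC
   disproportionality ratio.

3. **Inter-individual statistics** — OLS associations of descriptors with
   habitual intake, Benjamini–Hochberg FDR control (plus a documented
   `rank_scaled` variant), and pointwise paired condition contrasts across
   the sampling grid.

## Worked example

```python
from xanpk import generate_cohort, simulate_study, nca_table, summarize_nca

cohort   = generate_cohort(n=20, seed=1)          # weights ~ N(76.2, 8.7) kg
profiles = simulate_study(cohort, noise_cv=0.1, seed=1)
print(summarize_nca(nca_table(profiles)).round(3).to_string(index=False))
```

prints (abridged):

```
 analyte                   metric  n_used  n_excluded  median    q1    q3    mean     sd
caffeine              peak_time_h      20           0   1.750 1.750 1.750     NaN    NaN
caffeine              half_life_h      20           0   4.245 3.447 5.029     NaN    NaN
caffeine                kel_per_h      20           0     NaN   NaN   NaN   0.163  0.058
caffeine         peak_level_ug_ml      20           0     NaN   NaN   NaN   5.558  2.367
caffeine overnight_residual_ug_ml      20           0     NaN   NaN   NaN   0.604  0.445
```

Reading it: every subject's observed caffeine Tmax is 1.75 h — the true peak
(~1 h after a fast-absorbed capsule) falls before the earliest post-dose
sample, so the grid censors it; the C50 half-life centres near the
generating population value of 4.33 h; and the overnight residual is
positive for essentially everyone — ten days of thrice-daily dosing never
returns the morning level to zero.  Paraxanthine rows (not shown) have many
`n_excluded` half-lives: the metabolite declines so slowly ("flip-flop"
kinetics, terminal slope = min(ke, km)) that it often never reaches half of
its maximum within the 12 h of post-dose sampling.

The `examples/` directory has one short script per capability (single-dose
kinetics, study simulation, NCA tables, associations with FDR, condition
contrasts).  A thin CLI chains the stages:

```bash
xanpk run-all --seed 1 --out results/run1   # simulate -> NCA -> stats -> manifest
```

Outputs are plain CSV plus a JSON manifest from which the entire bundle can
be regenerated byte-identically.

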