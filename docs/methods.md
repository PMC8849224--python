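# Methods

## Kinetic model

The simulator uses a linear cascade with first-order steps:

    gut --ka--> parent --fm·ke--> metabolite --km--> eliminated
                  |--(1−fm)·ke--> other routes

For a single oral dose D the parent concentration is the Bateman function
and the metabolite the triple-exponential cascade solution (a third-order
divided difference of e^(−x·t) over the nodes ka, ke, km).  Both are scaled
by *apparent dilution volumes* `v_parent`, `v_metab` that map mg to
salivary μg/ml; they deliberately fold bioavailability and the
saliva:plasma partition ratio into one factor each, because the simulated
assay measures saliva only and the two factors are not separately
identifiable from such data.

Assumptions worth stating plainly:

* **Linearity.**  Dose superposition holds exactly; a multi-dose profile is
  the sum of shifted single-dose curves.  Real repeated caffeine intake
  shows dose-disproportional accumulation (CYP1A2 saturation/inhibition at
  higher exposure); the simulator's linearity is a modelling choice, not a
  claim about real data.  Michaelis–Menten kinetics, genotype strata and
  circadian clearance modulation are out of scope.
* **Flip-flop terminal phase.**  The metabolite's late log-slope equals
  min(ke, km).  With the defaults (parent half-life 4.33 h, metabolite
  7.79 h) km < ke, so paraxanthine outlives caffeine, which drives the
  elevated deprivation-window metabolite levels.
* **Near-equal rates.**  When any pair of (ka, ke, km) differs by less than
  1e−8 relative, the confluent (derivative) limit forms are evaluated
  instead of the generic formula; the closed forms stay continuous in the
  parameters.

## Study design emulated

Three within-subject conditions over 10 days, dosing at 0.75, 4 and 8 h
after waking (wake every 24 h): `caffeine` (150 mg × 3/day throughout,
450 mg/day), `placebo` (0 mg), and `deprivation` (active dosing truncated
so that day-10 sampling covers 24–43 h after the last active dose; with the
default offsets the last active capsule is the first one of day 9).

**Sampling grid.**  The exact clock times of the study's 11 saliva samples
are not published; the constraints are 11 samples, 105–120 min intervals, a
pre-dose baseline (~17 h after the previous day's last capsule), an
earliest post-dose sample at 1.75 h, sampling "until 12 h" after the last
capsule, and a deprivation window of 24–43 h.  The default grid satisfies
all of them simultaneously with two even blocks anchored to the final wake
time: five 1.8 h steps from wake+0.75 h (baseline, 16.75 h after the prior
day's last capsule) to wake+9.75 h (= last capsule + 1.75 h), then five
2.0 h steps to wake+19.75 h (last capsule + 11.75 h).  The block span of
19 h is what makes the deprivation window come out at exactly 24–43 h.  A
single evenly-spaced grid cannot place a sample exactly 1.75 h after the
last capsule, which is why the grid is two-block; it remains configurable
for sensitivity analyses.

## Population generator

Defaults are the study conditions: n=20; weight ~ Normal(76.2, 8.7) kg
truncated above 40 kg by redraw; habitual intake ~ Uniform(300, 600)
mg/day (a per-kg Uniform range can be substituted for recovery
experiments).  Habitual intake per kg acts linearly on the half-lives,

    HL_i = HL_pop + β · (x_i − x̄),   β = −0.11 h (parent), −0.14 h
    (metabolite) per mg/kg/day,

then ke = ln2/HL, multiplied by median-preserving log-normal noise,
exp(σZ) with σ² = ln(1+CV²).  The CVs of ke, km and the volumes default to
0.3 — chosen once to give dispersion of the same order as the reported
cohort statistics (K_el 0.14 ± 0.05 implies CV ≈ 0.36; part of the observed
spread is the covariate effect).  The apparent volumes default to
v_parent = 43.1 L and v_metab = 19.6 L, calibrated once so that the
noise-free day-10 Cmax of a population-typical subject is 5.2 (caffeine)
and 11.2 (paraxanthine) μg/ml on the default grid.

Randomness: one master seed; per-subject child streams via
`SeedSequence.spawn`, so enlarging a cohort never reshuffles earlier
subjects.  Assay noise streams are derived per (subject, condition).

**Assay model.**  Multiplicative log-normal error with mean 1
(`exp(σZ − σ²/2)`) and nominal CV; LLOQ censoring at 0.04 μg/ml (caffeine)
and 0.02 μg/ml (paraxanthine), the calibrator floors of the emulated
LC-MS/MS assay.  Censored values are stored as 0 with a flag.

**What the generator does not emulate:** non-linear accumulation, smoking
and contraceptive effects on clearance, irregular real-world dosing and
sampling times, assay heteroscedasticity beyond constant CV, and any
sleep/wake effect on kinetics.  Tests passing on these synthetic cohorts
demonstrate the estimators' correctness and calibration under the stated
model, not the physiological accuracy of the model itself.

## NCA descriptors

* **Cmax/Tmax**: maximal uncensored level strictly after the last dose;
  ties to the earliest sample.  Tmax is grid-censored from below by the
  first post-dose sample (1.75 h by default) — the estimator reports what
  the grid can see, matching how such designs are analysed.
* **C50 half-life**: time from the peak sample to the first crossing of
  Cmax/2, interpolated log-linearly between the bracketing samples (exact
  for exponential decline; a linear-interpolation switch exists for
  sensitivity).  If the profile never crosses C50 within the grid the value
  is NaN, excluded pairwise from summaries with counts reported — on the
  default grid this is common for the metabolite, which is a property of
  the design, not a failure.  Note the C50 half-life is unbiased for the
  terminal half-life only where the decline from the peak is
  mono-exponential; when the peak region still carries a faster exponential
  (absorption for the parent; parent elimination for the metabolite) it is
  biased upward by roughly 1/(R·ln2), R the ratio of the competing to the
  terminal rate.  The estimator-recovery computations therefore sample the
  terminal phase, entered after 8 time constants of the fastest competing
  exponential, where the residual bias is < 0.1%.
* **K_el**: minus the OLS slope of ln C on t over all uncensored positive
  samples strictly after Tmax, minimum 3 (the 11-sample grid leaves too few
  points for a terminal-phase selection heuristic).  Note that a C50
  half-life of 4.33 h and a mean K_el of 0.14/h are not related by
  ln2/K_el on sparse noisy grids; the two estimators answer different
  questions and both are reported.
* **AUC**: plain trapezoid; censored samples enter as 0 (bias bounded by
  LLOQ × window).  AUCc spans the caffeine-condition grid (baseline to
  ~12 h post dose), AUCw the deprivation grid (24–43 h).
* **Overnight residual**: the baseline-sample concentration (censored → 0).
* **Disproportionality**: AUCc(paraxanthine)/AUCc(caffeine) per subject;
  NaN for a non-positive denominator.  Cohort means of ratios are not
  ratios of means.

Summaries follow the conventional table shape for this design: median (IQR)
for peak time and half-life, mean ± SD (min–max, SD with n−1) for the rest.

## Statistics

Associations are ordinary least squares with two-sided t-tests — the
continuous-outcome, identity-link case of the generalised linear
regressions such studies report.  The canonical family is the three tests
(caffeine half-life, paraxanthine half-life, AUC ratio vs habitual
mg/kg/day), FDR-adjusted together.  `bh_adjust` offers the standard
Benjamini–Hochberg step-up adjustment (default) and a `rank_scaled`
variant, p·m/rank without the step-up minimum: the variant is not a proper
FDR adjustment (it is non-monotone) but is exposed because published
q-values sometimes follow it; with ties it uses the larger rank.

Condition contrasts are paired t-tests per grid point with BH correction
across the grid — a deliberately simple substitute for a mixed-model
condition × time analysis, which is explicitly out of scope.  Degenerate
inputs (all-zero differences → t=0, p=1; single subject → NaN, excluded
from adjustment) are handled as values, not exceptions.

## Numerical and design choices

* Problem sizes: recovery experiments use 500 cohorts of n=20 and the
  calibration check 2,000 null cohorts — enough for Monte-Carlo standard
  errors well inside the bands being checked.
* The ODE integrator (LSODA, rtol 1e−10) appears only in tests as an
  independent oracle for the closed forms; the implementation never
  integrates ODEs.
* The pipeline writes CSV + a JSON manifest; re-running from the manifest
  reproduces every output byte-identically (tested).
* Units are μg/ml and hours everywhere internally; ng/ml input is converted
  on read (flag or per-row units column).

## Known limitations

* Placebo profiles are exactly zero before noise, so multiplicative noise
  leaves them zero and fully censored; additive baseline noise is not
  modelled.
* The C50 half-life on the default 11-sample grid is undefined for most
  simulated paraxanthine profiles (see above); cohort-level metabolite
  half-life summaries from such grids rest on the few subjects whose
  profiles do cross, and real-data values reflect the same censoring.
* `kel_loglinear` can return negative estimates on noisy, slowly-declining
  profiles; they are reported as-is rather than truncated.
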