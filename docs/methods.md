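# Methods

## Structural model

Plasma concentration after a single intramuscular (extravascular) bolus
is described by a one-compartment model with first-order absorption and
first-order elimination:

    C(t) = (D/BW) / (V/F) · ka/(ka − ke) · (e^{−ke·t} − e^{−ka·t}),
    ke = (CL/F) / (V/F)

Bioavailability F is not separately identifiable after extravascular
dosing alone, so volume and clearance are apparent quantities ("/F").
Units are pinned and converted explicitly: time h, concentration ng/mL,
dose mg, body weight kg, V/F L/kg, CL/F reported in mL/min/kg and
carried internally in L/h/kg (factor 0.06). Body weight enters only
through D/BW; the model is otherwise per-kg.

When |ka − ke|/ke < 1e−6 the general formula is numerically 0/0 and the
analytic limit C(t) = (D/BW)/(V/F) · ka·t·e^{−ka·t} is used; the two
branches agree to better than 1e−6 relative at ka/ke = 1 ± 1e−7.
Flip-flop kinetics (ka < ke, terminal slope governed by absorption) is
permitted — corticosteroid ester depots in muscle plausibly absorb more
slowly than the drug is cleared, and the sampled population does produce
such individuals.

Default parameters (package constants, `TABLE_POP`): typical values
tvKa = 8.34 /h, tvV/F = 27.9 L/kg, tvCl/F = 10.1 mL/min/kg; log-scale
between-subject variances ω²(Ka) = 0.5969, ω²(V) = 0.1233,
ω²(Cl) = 0.0492; proportional residual SD stdev0 = 0.187. These imply
ke = 0.0217 /h, a 31.9 h elimination half-life, and
AUC∞ = (D/BW)/(CL/F) = 59.3 ng·h/mL for 20 mg to a 556.5 kg horse.

The between-subject variability values are interpreted as VARIANCES of
the log-scale random effects, not SDs — the convention of NLME software
ω² output, and the interpretation under which the simulated
99th-percentile detection time lands near the reported ~10-day mark
(the SD interpretation gives ≈150 h, far off). Random effects are
independent (no correlation structure is estimated or simulated).

## Non-compartmental analysis

- Cmax/Tmax: maximum observed quantifiable concentration; ties broken
  by earliest time.
- λz: OLS of ln C on t over candidate windows — all suffixes (≥3
  points) of the quantifiable observations strictly after Tmax, never
  including the Tmax point. The window maximizing adjusted R² wins;
  ties within 1e−4 favor more points; a nonnegative best slope raises
  terminal-phase-not-estimable. This mirrors the dominant "best fit"
  convention of commercial NCA software.
- AUC: linear trapezoid while concentrations rise or touch zero,
  logarithmic trapezoid (C1−C2)·Δt/ln(C1/C2) while they fall
  (linear-up/log-down); profile anchored at (0, 0).
- Extrapolation: AUC∞ = AUClast + Clast/λz with Clast the observed
  (not λz-predicted) last quantifiable concentration; a toggle is
  deliberate future work, the observed convention is the default.
- BLQ handling: a pre-dose BLQ anchors (0, 0); embedded and trailing
  BLQ points are excluded from regression and integration.

On dense noise-free model output the NCA recovers ke, t½ and AUC∞
within 1% of the closed forms (tested).

## Population simulation and detection time

Individuals are sampled as p_i = tv_p·e^{η_i}, η_i ~ N(0, ω²_p),
independently per parameter, with a fixed body weight of 556.5 kg
(optional Normal(556.5, 58.4²) sampling behind a flag, off by default).
Residual (assay) error is multiplicative, truncated at −1, and OFF by
default for detection-time work: the regulated quantity is the horse's
true plasma concentration, not a re-assayed value.

Detection times: 1000 individuals are simulated on a 0–408 h grid in
3-h steps; at each grid time the empirical 50th and 99th percentiles
are taken (numpy's linear-interpolation quantile definition, fixed);
each percentile curve's crossing of the 0.1 ng/mL screening limit is
located at the last grid point still at or above the limit and refined
by log-linear interpolation (exact for mono-exponential decay). The
last down-crossing is used so early pre-peak times below the limit
cannot shadow the terminal crossing. The withdrawal recommendation is
ceil(t99/24) whole days.

Monte Carlo noise matters at the tail: at n = 1000 the 99th-percentile
crossing has an across-seed SD of about 7 h (its large-n limit under
the default parameters is ≈232 h, crossing the 10/11-day boundary in a
minority of seeds). The acceptance script therefore pools 20 replicate
simulations; single runs are fine for exploration.

## Two-stage estimation

A full first-order-conditional (FOCE) mixed-effects estimator is
deliberately not re-implemented. With the rich 27-point per-horse
schedule, individual parameters are well identified, so a two-stage
procedure is used:

1. Per horse, minimize Σ(ln C_obs − ln C_pred)² over (ka, CL/F, V/F) —
   log-scale least squares, the criterion matched to multiplicative
   error. Parameters are optimized on the log scale (positivity by
   construction) with Nelder-Mead, xatol 1e−10, and three jittered
   restarts on non-convergence. BLQ points are excluded; profiles with
   fewer than 4 quantifiable points are rejected.
2. Pool: typical values are geometric means; ω̂² are log-scale sample
   variances (n−1); stdev0 is the pooled root mean squared log
   residual; CV% of a typical value is 100·sd(ln p)/√n.

Starting values come from NCA summaries: ke0 from λz, V0 from
(D/BW)/Cmax (bounded to [1, 500] L/kg), and ka0 by inverting
tmax = ln(ka/ke)/(ka − ke) via Brent's method (a coarse
max(5·ke0, 1/tmax) rule, capped at 50 /h, is the fallback — on fast
absorbers that rule alone underestimates ka severely).

Two-stage estimation is known to inflate between-subject variances by
the individual-estimation noise; this is most visible for ω²(Ka), where
only a handful of samples precede the ~45-min peak. Clearance and
volume — the parameters that drive the detection time through ke — are
recovered with median absolute error under 10% / 15% across replicate
12-horse cohorts (tested), and the refit population reproduces the
generating model's t99 with a median error under 15%. A single 12-horse
cohort carries ≈12% intrinsic sampling noise on ke (standard errors of
mean ln CL and ln V), so closure is assessed as a median across
cohorts, not per cohort.

Model comparison: per-subject AIC = n·ln(SSR/n) + 2k summed across the
cohort; lowest total wins, exact ties flagged. A no-absorption
mono-exponential candidate is provided as a deliberately simpler
comparator.

## Biomarker and electrolyte statistics

The baseline-versus-time analysis is the classical balanced
one-within-factor repeated-measures ANOVA (SS partitioned into subject,
time, residual; F = MS_time/MS_residual on (t−1), (n−1)(t−1) df) —
exactly the random-intercept mixed model for balanced data, which the
study design is. Post hoc, each post-baseline time is compared with
baseline by a paired t-test on within-subject differences; p-values are
multiplied by the number of post-baseline comparisons (Bonferroni,
capped at 1). Dunnett's correction would be less conservative but
Bonferroni is the stated convention this pipeline reproduces. Subjects
missing a baseline are dropped with a warning; otherwise-unbalanced
data fall back to complete-case ANOVA with pairwise-complete post hoc
tests and per-comparison n reported. The implementation is checked
against statsmodels' AnovaRM as an independent oracle.

Fractional excretion: FE = [(U_x/P_x) ÷ (U_cr/P_cr)] × 100, invariant
to any common rescaling of the analyte pair or the creatinine pair.
The pre/post electrolyte analysis is the two-time-point special case
(one comparison, Bonferroni factor 1).

Censored summaries report mean ± SD over above-LOQ values with
above-LOQ/total counts; an all-censored time point is "ND".

## Synthetic data generator

The generator emulates the study design, not its raw data: 12 horses,
20 mg IM, plasma sampling at 5/10/15/30/45 min then 1–312 h (27
points), urine at 24–360 h, plasma/urine LOQ 0.01/0.05 ng/mL.

- Plasma: population model draw + multiplicative stdev0 noise + LOQ
  censoring (censored rows carry an empty value and a flag, never 0).
- Urine: U(t) = U24·e^{−kz(t−24)} with ln U24 ~ N(ln 13, 0.5²),
  kz ~ N(0.012, 0.002²)/h and log-normal noise (SD 0.25), censored at
  0.05 ng/mL — chosen so above-LOQ counts decline to ~0 by 360 h and
  the 24-h mean sits near the study's reported level.
- Cortisol: baseline B ~ N(52.0, 10.3²) ng/mL and
  value = B·(1 − S(t))·(1 + ε), ε ~ N(0, 0.1²). S(t) is a shape
  template, not a PD model: a sustained plateau (0.65 after a 9.2/h
  first-order onset) plus a log-time Gaussian bump (width 0.6) peaking
  at 0.9 at the 36-h nadir, so suppression stays above 0.6 from 30 min
  through 312 h and the sampled nadir is genuinely peaked rather than
  noise-dominated. Setting the maximum suppression to 0 gives the null
  (flat) mode used for calibration.
- Electrolytes: plasma values are Normal draws around the pre/post
  targets (potassium 3.8 ± 0.71 → 2.7 ± 0.67 mmol/L, etc.); each
  analyte's FE is a log-normal draw around its target median
  (potassium 39% → 69%) and the urine concentration is back-computed
  from the FE identity given shared per-horse creatinine draws. The
  null mode re-draws the post phase from the pre distributions.
  (Published text and table disagree on which SD accompanies pre/post
  potassium — 0.67 vs 0.71; the table values are used.)

Each generator draws from an independent, seed-derived stream, so
regenerating one dataset never perturbs another.

What passing tests on synthetic data do NOT show: the generators have
no assay drift, no inter-occasion variability, no parameter
correlations, no mechanistic PD link between drug concentration and
cortisol or electrolytes, and urine is an empirical decline rather than
an excretion model. Results on real study data depend on those features;
the tests establish the correctness of the computations, and
calibration/power of the statistics, under the stated design.

## Numerical choices and degenerate inputs

- ka = ke ridge: relative tolerance 1e−6 switches to the analytic
  limit; tmax limit is 1/ka.
- Quantiles: numpy "linear" method, fixed for reproducibility.
- Crossing interpolation: log-linear; a curve that never reaches the
  limit returns 0; a curve still at/above it at 408 h raises
  grid-too-short rather than extrapolating.
- λz ties: adjusted-R² ties within 1e−4 resolved toward more points;
  windows need ≥3 points.
- RM-ANOVA with zero residual mean square (all values identical)
  reports F = 0, p = 1 rather than NaN.
- All randomness flows through numpy Generators seeded explicitly;
  cohort simulation is bitwise reproducible under (seed, n, grid).

## Known limitations

- Two-stage ω² estimates are inflated by individual-fit noise
  (materially so for ka); a FOCE/EM estimator would be the upgrade
  path.
- Only the multiplicative residual structure is implemented; the
  additive and mixed candidates are out of scope.
- No confidence intervals are attached to detection times; replicate
  seeds quantify Monte Carlo spread but not parameter uncertainty.
- Urine is summarized (censored means, counts), never modelled for
  detection; two-compartment closed forms and repeat dosing are out of
  scope.
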