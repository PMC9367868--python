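# Methods

This note documents the models implemented in `shelfkin`, the conventions
and numerical choices behind them, and what the synthetic-data generators
do and do not emulate.

## Primary growth model (Baranyi–Roberts)

Microbial counts on the log10 scale are described by the explicit
Baranyi–Roberts solution with curvature parameter m = 1 and transition
rate ν = μmax (the DMfit-compatible convention). Working in natural-log
concentration, ỹ = y·ln10 and μ̃ = μ·ln10,

    ỹ(t) = ỹ0 + μ̃·A(t) − ln(1 + (e^{μ̃·A(t)} − 1)/e^{ỹmax−ỹ0}),
    A(t) = t + (1/μ̃)·ln(e^{−μ̃t} + e^{−h0} − e^{−μ̃t−h0}),   h0 = μ̃·λ.

The parameters are the initial level y0 (log10 CFU/g), the carrying
capacity ymax, the maximum rate μ (log10 CFU/g per day) and the lag λ
(days). A(0) = 0 forces y(0) = y0 exactly; A(t) → t − λ as t grows, so
the lag delays the exponential phase. Both sums inside the logarithms are
evaluated with `logaddexp`/`log1p`-style rearrangements whose terms are
all positive, so the solution is stable for any admissible parameters.
Because A(t) approaches t − λ only asymptotically, threshold-crossing
times sit slightly (O(e^{−μ̃λ}/μ̃)) before the idealized "lag + linear
phase" value.

Rates are treated as log10 CFU/g per day throughout. Published tables in
this domain often print d⁻¹; the log10 interpretation is the one
consistent with log-count plots and with the shelf-life formula below.

**Fitting.** Nonlinear least squares (`scipy.optimize.least_squares`)
on the log10 scale with three perturbed restarts. Start values: y0 from
the first observation, ymax from the maximum, μ from the steepest
two-point slope, λ from the first time the series exceeds y0 + 0.2.
Bounds: μ ∈ (0, 10], λ ∈ [0, t_max], ymax ∈ [max obs − 0.2, max obs + 2]
(the upper margin keeps ymax identifiable when the plateau is barely
reached). With `with_lag="auto"` both variants are fitted and the lag is
kept only if an extra-sum-of-squares F-test at α = 0.05 finds it
significant — mirroring the common practice of dropping a
non-significant lag; a lag pinned at the zero bound likewise falls back
to the no-lag variant and is flagged. A series that never rises 0.2
log10 above its first observation raises a no-growth error (0.2 log10 is
below typical plate-count noise, so flat and decreasing series are
rejected without discarding genuine slow growth). Standard errors come
from the Gauss–Newton covariance s²(JᵀJ)⁻¹; R² is 1 − SSres/SStot on
log10 counts.

## Secondary model (Arrhenius)

Growth rates follow ln k = ln k_ref − (Ea/R)(1/T − 1/T_ref) with
T_ref = 4 °C (277.15 K), the conventional chill-chain reference. The fit
is ordinary least squares of ln k on (1/T − 1/T_ref) — unweighted by
default because replicate-level data are usually unavailable;
inverse-variance weighting on the log scale, w = (k/se)², is available
when standard errors are supplied. Ea = −R·slope for rate-like
quantities.

**Sign convention for time-like quantities.** Lag phases and TTI
response constants are time-like: they lengthen as temperature drops.
Their temperature factor is therefore exp(+(Ea/R)(1/T − 1/T_ref)) — the
reciprocal of the rate factor. Formulas in the applied literature
sometimes print the rate-like sign on lag terms; applied literally that
would shorten lags in colder storage, contradicting every chill-storage
dataset, so this package normalizes the sign and states the convention
here rather than silently switching per call site.

The reference lag λ_ref shares the rate model's Ea (a single Ea per
organism/packaging) and is estimated by the geometric mean
λ_ref = exp(mean_i[ln λ_i − (Ea/R)(1/T_i − 1/T_ref)]); temperatures with
no identifiable lag are simply omitted, and an all-absent set yields
λ_ref = 0 with a flag.

## Shelf life

    t_SL(T) = (logN1 − logN0)/k(T) + λ_ref·exp(+(Ea/R)(1/T − 1/T_ref))

with the acceptability limit logN1 = 7 log10 CFU/g for total viable
counts (the standard spoilage-rejection level for chilled fish) and
logN0 the initial load. For the reference seabream datasets the initial
TVC load is taken as 5.0 log10 CFU/g, the study's representative fresh-
fillet level (batch initials ranged 4.5–5.4; the choice is a spec input,
not an output of the fit). Temperatures outside the 0–10 °C calibration
range warn (extrapolation); outside −5..25 °C they error.

## TTI response kinetics

The color state of an enzymatic label is summarized by the CIELab sum
(a + b), min–max normalized to [0, 1] (Eq. norm = ((a+b) − min)/(max −
min), clipped). By default the calibration extremes are the series' own
min/max — a per-batch self-calibration — and can be overridden by an
external calibration, since practice varies and the raw extremes depend
on the batch.

Against time the response is the rising logistic
norm(t) = 1/(1 + exp((k1 − t)/k2)): k1 is the inflection time (days),
k2 the spread (1/k2 the exponential-phase slope). This is the only
parsing of the exponent that yields a rising sigmoid with k1 as a time
constant. The visual end point (orange–red) corresponds to norm = 0.8,
so the response time is t = k1 + k2·ln 4 (configurable endpoint).
Fitting is least squares in (ln k1, ln k2) (positivity by construction);
a series must have ≥ 5 points and span at least 0.5 of the response
range, otherwise it is degenerate.

**Global model.** Across enzyme concentration C and temperature,

    k_i(C, T) = k_iref(C=1U)·C^(−α_i)·exp(+(Ea/R)(1/T − 1/T_ref)),

one Ea per chemistry (the substrate sets the temperature sensitivity,
the enzyme load the response time). k1 and k2 are time-like, hence the
positive exponent — published forms sometimes print the rate-like sign,
which contradicts the measured constants falling with temperature. The
default estimator is a joint log-linear least squares of ln k1 and ln k2
on ln C and (1/T − 1/T_ref) with a shared Ea slope and separate
intercepts/concentration exponents: closed-form, reproducible, and exact
on noiseless data. A direct nonlinear fit to normalized responses
(`fit_to_responses`) is provided for when raw response curves are
available; it refines the log-linear solution. The two concentration
exponents are always estimated separately — equality is never assumed
even if a particular dataset reports them equal.

## TTI–product matching

Two criteria. (1) Hard filter: |Ea_product − Ea_TTI| ≤ 20 kJ/mol, the
standard compatibility window for integrators. (2) Ranking: over a
0–10 °C grid at 0.5 °C steps, candidates are ordered by the maximum
absolute relative deviation between the label's end-point time and the
product's shelf life, max_T |(t_TTI − t_SL)/t_SL|. The published
selection procedure judges the curve match visually; the max-relative-
deviation statistic is this package's quantitative stand-in, so selection
results are asserted at top-2 rather than top-1 level. Ties favor labels
that are conservative at abuse temperatures (label expires at or before
the shelf life for all grid temperatures above 6 °C).

## Non-isothermal prediction

Temperature histories are piecewise-constant logger profiles. The
effective temperature solves

    exp(−(Ea/R)(1/T_eff − 1/T_ref)) = (1/D)·Σ_i d_i·exp(−(Ea/R)(1/T_i − 1/T_ref))

in closed form; for Ea → 0 the inversion degenerates and the duration-
weighted arithmetic mean is returned by convention (the continuous limit
of the formula). T_eff always lies within [T_min, T_max] and, for
Ea > 0, at or above the arithmetic mean (Jensen).

Growth under a profile integrates the differential Baranyi system with
the lag carried by the physiological state q:

    dp/dt = μ̃(T(t)),    dỹ/dt = μ̃(T(t))·expit(p)·(1 − e^{ỹ−ỹmax}),

with p = ln q and q(0) = 1/(e^{μ̃(T_ref)·λ_ref} − 1), so a constant
profile at T_ref reproduces the isothermal explicit solution to solver
precision. How lag history should be carried across temperature shifts
is not settled in the literature; the q-state formulation is the
standard choice and is what is implemented. Zero lag maps to p0 = 50
(expit saturates to 1 in double precision). Integration is per segment
with DOP853 at rtol 1e-11/atol 1e-12, so piecewise-constant rate jumps
never cross a solver step.

Validation uses RE% = |(k_exp − k_pred)/k_exp|·100 with the 20%
applicability criterion; RE is reported as a magnitude and rounded to
the nearest integer percent for display, full precision retained
internally. Both experimental and predicted rates are obtained the same
way — a Baranyi fit to the curve — so the comparison is like for like.

## Synthetic data

The generators emulate the study design: Baranyi-shaped log10 count
curves with additive iid Gaussian noise on the log scale (0.15 log10
CFU/g by default, a typical plate-count repeatability at these levels;
no detection-limit censoring), at 0/2.5/5/10 °C with ~10–12 sampling
points over 0–25 days; logistic TTI responses with additive Gaussian
noise (sd 0.03) on the normalized response, mapped back through the
calibration to raw (a+b) readings; and constant, square-wave or
staircase profiles within 0–10 °C, with the square wave's dwell fraction
solvable by bisection to hit a requested T_eff (the validation scenario
uses 4.8 °C) within 0.01 °C. All generators are pure functions of
(parameters, seed).

What they do not emulate: replicate correlation within a sampling day,
detection limits and plate-count discreteness, microbial interactions,
headspace-gas dynamics, or TTI activation delay. Passing recovery tests
therefore shows the estimators are consistent under the model's own
assumptions with realistic noise — not that real curves are free of
model misspecification.

## Problem sizes and tolerances

Solver cross-checks compare the explicit Baranyi solution against an
independent integration of the differential form over 50 random
parameter draws (tolerance 1e-6 log10 over the whole growth window).
Recovery experiments use 100 seeds; medians are asserted (individual
noisy fits can be far off when the lag and rate trade off at high
noise). Threshold crossings are bracketed to better than 1e-9 days.
The acceptance script reruns every headline quantity from scratch in
about 20 s on one core.

## Known limitations

* Lag under dynamic temperatures uses the q-state convention; other lag
  carry-over rules would give different non-isothermal predictions.
* The Arrhenius refits of published rate tables are unweighted; the
  original fits may have used replicate-level weighting, which is why
  refitted Ea values are only required to agree within 15%.
* Only the microbial (TVC) shelf-life criterion is implemented; sensory
  and chemical freshness indices are out of scope.
* No bootstrap/profile-likelihood uncertainty; standard errors are
  asymptotic.
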