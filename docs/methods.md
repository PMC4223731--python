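# Methods

## The on-kinetics model

At exercise onset, oxygen uptake is modelled as a three-parameter
asymptotic (mono-exponential) rise

VO2(t) = y₂ − (y₂ − y₁)·e^(−t/τ),

with y₁ the lower limit at t = 0 (resting VO2), y₂ the upper limit
(steady-state VO2) and τ > 0 the time constant, t counted in minutes from
walk onset. The cardiodynamic phase-I delay (~20 s) is not modelled: in
breath-by-breath walk data it is rarely distinguishable from the phase-II
exponential, and a delayed four-parameter model is markedly less stable.
The cost is a possible slight upward bias in τ; the generator's optional
`delay` parameter exists precisely to quantify that bias in simulation.
Because no delay is fitted, the mean response time (MRT) equals τ, and the
rise fraction at t = MRT is 1 − 1/e ≈ 63.2 % identically.

Derived indices, all exact algebra on the fitted parameters: oxygen deficit
O2def = τ·(y₂ − y₁) (the closed form of ∫₀^∞ (y₂ − VO2(t)) dt); wMRT =
MRT/(y₂ − y₁), using the rest-to-steady-state rise ΔVO2 as the work-rate
proxy for a self-paced walk, in min²/ml. VO2ss and VO2rest used in the
indices are the fitted ŷ₂ and ŷ₁, not window means, so O2def = MRT·ΔVO2 and
wMRT = MRT/ΔVO2 hold to machine precision.

## Preprocessing

Walk-phase breaths are averaged over consecutive half-open windows
[k·w, (k+1)·w) anchored at walk onset, default width w = 20 s (an 18-point
series for a six-minute walk). Windows are time-anchored and unweighted;
a trailing partial window is kept if it holds a breath; empty windows are
dropped with a warning and a series with more than 20 % empty windows is
flagged unusable. Window width is a configuration setting: narrower
averaging (e.g. 18 s) is available but changes nothing qualitative —
noiseless-exponential tests show the 20 s smoothing moves the recovered τ
by well under 1 % relative to fitting raw breaths.

Resting VO2 is the mean of the last "stable" 60 s segment of the seated
rest phase, where stability means a rolling 60 s coefficient of variation
below 10 %. The CV criterion is this package's operationalisation of
"stable resting values"; both the window and the threshold are
configurable, and an unstable rest raises a distinct error so callers can
fall back to a plain final-minute mean deliberately.

## Fitting

Parameters are estimated by unweighted nonlinear least squares using the
standard Gauss–Newton iteration with step halving: the linearised step is
solved from the analytic Jacobian, halved while it would increase the SSR
or drive τ non-positive, and iteration stops when the relative SSR change
falls below 1e-8 (cap 50 iterations, 30 halvings per step).
Initialisation: y₁ from the first window, y₂ from the mean of the final
two minutes, τ from the observed time to half rise divided by ln 2.
Non-convergence is reported, not raised; a converged fit with ŷ₂ ≤ ŷ₁
raises a degenerate-fit error since every derived index is then undefined.
Standard errors come from (JᵀJ)⁻¹·s² at the solution. An independent
optimizer (scipy's Levenberg–Marquardt) and a 50³ brute-force grid serve
as cross-checks in the test suite; they are never the implementation.

## Goodness of fit and quality control

Neill's lack-of-fit test is computed on the windowed residuals using
clusters of neighbouring design points as pseudo-replicates — by default
consecutive non-overlapping pairs of windows (the final cluster takes three
windows when the count is odd), injectable for other schemes. Pure error is
the within-cluster residual scatter (df n − m); lack of fit is the excess
of the residual sum of squares over pure error (df m − p, p = 3); their
mean-square ratio is referred to F. The test is reported "not computable"
(never p = 1) when clusters are too few or pure error is numerically zero.
Across a batch of fits, raw Neill p-values are multiplicity-adjusted
(Holm by default, Benjamini–Hochberg optional); an adjusted p < 0.05 flags
a curve but does not exclude it — lack of fit that materially distorts the
estimates shows up in the pattern classifier instead.

Two exclusion patterns dominate real walk tests, and the classifier mirrors
them. *No plateau* (steadily rising VO2, typically increasing pace): flagged
when 3τ̂ exceeds the walk duration, or when an OLS line through the final
two minutes of window means climbs faster than 50 ml/min per min with
slope p < 0.05. *Variable plateau* (pauses, variable pace): flagged when
the CV of window means after t = 3τ̂ exceeds 7.5 %. These thresholds stand
in for the visual review used in practice; they were chosen so the
generator's two failure modes are cleanly separable (both batteries run at
100 % in the acceptance script) and are configuration settings, not
constants.

## Effort criteria

ATS maximal-effort flags use strict inequalities: measured HRmax > 90 % of
predicted, VO2peak > 84 % of predicted, ventilatory reserve < 11 l/min or
< 15 % of capacity. Reference equations live behind a provider interface;
the defaults are HRmax = 220 − age, ventilatory capacity (MVV) = 35·FEV1
l/min, and predicted VO2max from the Wasserman/Hansen cycle equations.
Labs using different reference equations plug in their own provider;
missing metadata yields an "unknown" flag and the disjunction is taken
over the known flags only.

## Cohort statistics

Continuous variables pass a Shapiro–Wilk gate with rejection at p < 0.25 —
deliberately liberal, so mild non-normality is surfaced; the comparison
itself still runs on the linear-model path with the flag attached. Group
differences use a one-way linear model (ANOVA F) with uncorrected pairwise
contrasts from the pooled residual variance. Associations between wMRT and
exercise capacity (VO2ss, walk distance, MRT) are univariate OLS per group,
with wMRT rescaled by 10³ so slopes are on the conventional reporting
scale. Survival within the cardiac and non-cardiac strata splits at the
stratum's median wMRT (ties to the low arm), estimates Kaplan–Meier curves
per arm (lifelines), and tests the binary high/low covariate in a Cox
proportional-hazards model by Wald test; a continuous-covariate mode is
provided since published analyses are often ambiguous on this coding. With
zero events the Cox step is skipped with a notice.

## The synthetic-data generator

The generator emulates what the analysis consumes, not walking physiology:
a rest → 6-min walk → recovery session with gamma-renewal breath timing
(mean 22 breaths/min, CV 0.25 — positive, overdispersed, simple), walk VO2
following the mono-exponential with optional phase-I delay, additive
Gaussian per-breath noise, VCO2 = RER_target·VO2 (default 0.86, the
mean walk RER reported for such cohorts), heart rate ramping in parallel,
and SpO2 as constant plus noise. Failure modes: *no_plateau* adds a linear
drift (default 100 ml/min per min) over the whole walk; *variable_plateau*
superimposes square-wave dips (default two 20 s pauses at 50 % of the rise)
after 2τ. With drift 0 the failure series is bit-identical to the clean
series under the same seed.

Cohorts draw per-subject MRT and VO2ss from truncated normals at published
group means/SDs for healthy controls and four disease groups (COPD,
restrictive lung disease, pulmonary arterial hypertension, congestive
heart failure), truncated at MRT ≥ 0.2 min and ΔVO2 ≥ 100 ml/min to avoid
degenerate wMRT; rejected draws are resampled and counted. Resting VO2 is
drawn around 300 ml/min (a physiologic seated value; group tables rarely
report it, so this is an explicit assumption — it makes simulated wMRT
levels somewhat lower than published group means while preserving their
ordering: healthy lowest, PAH highest among patients). Follow-up events
come from an exponential hazard, log-hazard = group baseline +
hazard_link · standardized wMRT, censored at a truncated-normal follow-up
duration; hazard_link is 0 for the pulmonary groups and 0.6 for heart
failure, the simplest outcome model that reproduces the qualitative
finding that slowed kinetics carry prognostic weight only in cardiac
disease. What passing tests on these data do *not* show: robustness to
device drift, missing breaths, non-Gaussian noise, or genuinely biphasic
kinetics in patients — the generator is the analysis's assumptions made
executable, and the Neill power battery is the only place a deliberately
misspecified truth appears (fast+slow component, slow amplitude 30 % of
fast, τ = 0.3 and 4.0 min, window-level noise SD 15 ml/min).

## Problem sizes and numerical choices

Monte-Carlo batteries use sizes at which their Monte-Carlo error is small
against the quantity checked: 200 seeds for τ recovery and the QC
batteries, 1000 replicates for Neill calibration and power, 500 cohorts of
n = 60 for the null-Cox uniformity check, 50 cohorts of n = 500 for the
survival direction check, 10 cohorts of n = 500 for generator means. Seeds
are fixed in tests and derived from `--seed` in the acceptance script.
Ties at the wMRT median go to the low arm; empty KM arms (all-tied input)
are omitted rather than fitted; the Neill test's zero-pure-error guard
uses a relative tolerance so exactly-model-generated data report "not
computable" rather than a spurious p.

## Known limitations

Single mono-exponential only — no biphasic or recovery (off-kinetics)
fitting; fitting operates on window means, not raw breaths; no
multivariable or competing-risks survival models; reference-value equations
are pluggable defaults, not a validated library; the generator's group
presets summarise one published cohort and are not population references.
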