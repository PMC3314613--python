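# Methods

## The risk model

All three scores share the proportional-hazards survival form

    p(t | x) = 1 − S0(t) ^ exp(L − L̄),      L = Σ_j β_j x_j,

where the x_j are the equation's *terms*: continuous age (and, in the
women's original equation, age²), 0/1 indicators for the non-reference
NCEP total- and HDL-cholesterol categories and JNC blood-pressure stages,
diabetes, and current smoking.  The blood-pressure stage of a person is the
more severe of the SBP-implied and DBP-implied stages; category bins are
left-closed ([160, 200) is "160–199").  S0(t) is the survival at the mean
risk profile, so L is centred at L̄ = Σ β_j x̄_j.

The three scores differ only in where (β, x̄, S0) come from:

| score        | β          | x̄                | S0(t)                          |
|--------------|------------|-------------------|--------------------------------|
| original     | published  | source population | source value, horizon-rescaled |
| recalibrated | published  | target cohort     | target-cohort Kaplan-Meier     |
| refit        | Cox refit  | target cohort     | Breslow baseline at means      |

Horizon rescaling uses the exponential model S0(t) = S0(h)^(t/h).  The
default analysis horizon is 7.5 years — inside the follow-up of an elderly
cohort observed for ~8–10 years, avoiding extrapolation.

Assumptions: proportional hazards throughout; non-CHD death treated as
independent right-censoring (no competing-risk sub-distribution); the
event indicator is binary.

## Recalibration

`recalibrate` replaces the reference means with the cohort means of the
*transformed* terms (prevalences for indicators, mean age, mean of squared
ages — E[x²], not E[x]²) and the baseline survival with the cohort
Kaplan-Meier value at t (right-continuous step convention; events precede
censorings at tied times).  Because exp is strictly increasing and the
base S0 is a constant, per-person risk ranks are exactly preserved:
Harrell's C of original and recalibrated scores is identical to machine
precision, which the tests assert bit-for-bit.  A person at the cohort
mean profile receives risk exactly 1 − KM(t).

## Refit

`fit_cox` maximises the Efron partial likelihood (delegated to lifelines,
with the Newton convergence tightened to a 1e-10 step norm and the
relative-likelihood early stop disabled, so tiny-sample fits agree with
brute-force maximisation of the hand-written likelihood to ≤1e-4).  Efron
is the only tie rule exposed: the package's cohorts have continuous times
where Efron and Breslow coincide, and lifelines implements Efron only.
Zero-variance terms and event-free cohorts are rejected up front with
specific errors; a model with no terms is fitted as the null model with
the closed-form log partial likelihood −Σ_events log(risk-set size)
(Efron-corrected under ties).

The default per-sex term specs pool categories that hold too few events in
an elderly cohort, and drop total cholesterol and age² for women (both
unpredictive at these ages).  Exactly which sparse extreme cells are pooled
is a judgement call; the defaults are marked as inferred in their notes and
are plain data, fully overridable.  A practical warning encoded in the
tests: age and age² are nearly collinear on a ten-year age window
(r ≈ 0.99998), and retaining both can destabilise the fit — drop the
quadratic when refitting to a narrow age band.

Baseline survival at means is the Breslow cumulative-hazard estimator
evaluated at the covariate mean vector (the value lifelines computes as its
baseline); beyond the last observed time the last value is carried forward
with a warning, and the value is clamped into (0, 1) by 1e-12 at the
boundaries.

The proportional-hazards diagnostic regresses scaled Schoenfeld residuals
on a transform of event time (Kaplan-Meier transform by default; rank,
identity and log selectable).  Per-term statistics come from lifelines
(R's pre-2019 approximation); the global statistic is the
Grambsch-Therneau score test u'V⁻¹u / (d·Σ(g−ḡ)²) with u the
transform-weighted sum of scaled residuals and V the coefficient
covariance.  On a frozen fixture it agrees with an independent
survival-analysis implementation's global test within 5%, and under
proportional hazards its rejection rate at α = 0.05 is nominal in
simulation.

## Validation

**Harrell's C** uses the pair rule: a pair is usable when the shorter
observed time belongs to an event (tied times are not usable); it is
concordant when that subject has the strictly higher score, and score ties
count 1/2.  The implementation is a vectorised all-pairs scan (O(n²) in
512-row blocks — exact, no tree approximations) and is checked against a
literal enumeration oracle on random censored instances.

**Optimism correction** follows Harrell's bootstrap: refit on each
resample, optimism_b = C(resample model on resample) − C(resample model on
original), corrected = apparent − mean(optimism_b).  Resampling is plain
by-subject with replacement from a single integer seed; a failed resample
fit is redrawn (at most 2B attempts).

**Calibration** uses a censoring-aware Hosmer-Lemeshow chi-square:
subjects are split into `groups` (default 10) near-equal blocks of
increasing predicted risk (stable sort, so boundary ties split
deterministically); E_g = Σ p̂_i within the block; O_g = n_g·(1 − KM_g(t))
with the within-block Kaplan-Meier, which reduces to the raw event count
when nothing is censored before t; the statistic is
Σ (O_g − E_g)²/(E_g(1 − E_g/n_g)) on groups − 1 degrees of freedom.  The
groups-minus-one convention is adopted because it is the unique df under
which the published statistic/p pairs (4.89 → 0.844, 22.73 → 0.007,
16.11 → 0.065) are consistent; with in-sample risks its type-I error is
nominal in simulation.  Empty-expectation groups are merged downward and
the df reduced, with the merge count reported.

**Comparing two C indices** uses a subject-level bootstrap of the
difference with a two-sided quantile p-value.  Rank-equivalent scores give
a difference of exactly zero in every replicate and p = 1.  This choice of
test is the package's own (the comparison method behind published values
of this kind is typically uncited).

## Model selection

The screen fits one unadjusted Cox model per candidate and retains Wald
p < α (default 0.20); skewed laboratory values enter as logs, and lipids
and pressures enter continuously in the selection models (unlike the
categorical refit).  Backward elimination repeatedly drops the
largest-p term ≥ 0.10 and refits.  Forward stepwise greedily adds the
candidate with the largest AIC/BIC decrease, stopping when none decreases
it.  AIC = −2 logPL + 2k; BIC = −2 logPL + k·log(d) with d the event count
(the survival convention for effective sample size; configurable to n).
Stepwise is bounded below by exhaustive best-subset enumeration in the
tests, and BIC's selected set is verified to be a subset of AIC's on
seeded simulations.

## Synthetic cohort generator

`generate(spec, seed)` draws covariates from the spec's marginals —
truncated normals for continuous measures, with the parent location solved
so the *truncated* mean equals the target; categorical draws for sex,
smoking, race and the lifestyle covariates — optionally coupled through a
Gaussian copula over (age, TC, HDL, SBP, DBP).  Event times follow
hazard(t|x) = h0(t)·exp(η), η = β*'(z(x) − z̄), with z̄ the *analytic*
expected term means (truncated-normal bin probabilities; the BP stage uses
the independence of SBP and DBP), β* defaulting to the sex-specific Wilson
coefficients, and h0 exponential (Weibull selectable) with closed-form
quantile inversion.  Censoring is min(administrative, dropout):
administrative uniform on [8.0, 10.2] years — a stylised stand-in for
staggered entry — plus independent exponential dropout at 0.025/yr
mimicking non-CHD death in this age group.

The default baseline rates (0.0145/yr women, 0.0278/yr men) were solved
once by Brent inversion of the Monte-Carlo expected incidence
(`calibrate_baseline_rate`) so the 7.5-year cumulative incidence is 0.12 in
women and 0.21 in men — ~0.16 overall, ~350 events in a cohort of 2193 —
the regime the package is designed for.

What the generator does *not* emulate: joint covariate structure beyond
the optional copula; the age distribution's true dispersion — a mean of
73.5 with sd 2.85 on [70, 80) is unattainable for any truncated normal
(the uniform limit is 2.89 and the mean-constrained frontier lower), so
the generator matches the stated mean exactly and accepts sd ≈ 2.1;
time-varying hazards; dependent censoring; measurement error.  Passing
tests therefore demonstrate correctness of the pipeline's computations and
its qualitative transport behaviour, not fidelity to any particular real
cohort.

## Numerical choices and problem sizes

Risks are computed in double precision with no intermediate rounding.
Baseline survivals are clamped to (1e-12, 1 − 1e-12).  KM evaluation is
right-continuous; decile boundary ties break by stable sort on
(risk, position).  Newton fitting: step-norm tolerance 1e-10, maximum 500
iterations, lifelines step-halving.

Simulation-based test sizes are chosen so the whole suite runs in a couple
of minutes on one core while keeping Monte-Carlo noise well inside the
asserted bands: coefficient recovery uses 200 cohorts of n = 2000 (~420
events each; MC error of the mean bias ≈ 0.01), the calibration
operating-characteristics check uses 500 cohorts of n = 1000 (3-SE
binomial band ±0.029 around 0.05), and the transport demonstration uses
five cohorts of n = 2193 with the baseline hazard doubled, asserting the
fail/pass pattern on per-sex medians.
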