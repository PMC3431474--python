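# Methods

## Model structure and assumptions

The package implements survival models of the GUTS family for organisms
under time-varying chemical exposure. The organism is a single well-mixed
compartment that does not grow, moult-cycle or acclimatise during an
experiment; exposure is a piecewise-constant concentration time series
(left-closed/right-open segments, so the value *at* a breakpoint belongs to
the new segment — the convention the event-driven solver relies on). Units
are fixed package-wide: days; nmol/mL in water; nmol/g wet weight in tissue.

Internal concentration follows dC_int/dt = k_in C_ext − k_out C_int. The
loss rate constant k_out lumps elimination and biotransformation of the
parent compound; metabolites are not modelled separately. Two dose metrics
are available: scaled damage D* (full variants, driven by the
pre-calibrated C_int through dD*/dt = k_d (C_int − D*)) and scaled internal
concentration C*_int (reduced variants, driven directly by C_ext with the
dominant rate constant k_d). The reduced metric with k_d = k_out is exactly
C_int/BAF (substitute u = C_int/BAF into the one-compartment equation), so
the reduced model is the full model with the two first-order stages lumped
into whichever is slower.

Death follows one of two mechanisms. Stochastic death (SD): hazard
dH/dt = k_k max(metric − z, 0) + h_b, survival S = e^(−H); all organisms
share the threshold z and face the same risk. Individual tolerance (IT):
each organism has a fixed threshold drawn from a log-logistic distribution
with median α and width β; the dead fraction is the distribution's CDF at
the *running maximum* of the dose metric, and S = (1 − F) e^(−h_b t). The
background hazard h_b is treated as constant although the hazard
formulation would admit a time-varying one, because it is estimated from
control survival with a single-rate exponential model.

## Numerical approach

Every state equation is linear with piecewise-constant forcing, so each
exposure segment has a closed-form solution of the form
A + (p + q·τ)e^(−rτ) with at most two exponential rates (the t·e^(−kt)
form arises only in the equal-rate degeneracy |k_d − k_out| ≤ 1e−9·k,
where the code switches to the limit formula for stability). The solver
never discretises time:

* SD hazard — threshold crossings are bracketed on the (at most two)
  monotone pieces of a segment, located by Brent root-finding (xtol 1e−11)
  on the closed form, and the exceedance is integrated analytically between
  crossings;
* IT running maximum — interior extrema of each segment are located in
  closed form; the prefix maxima make F exact at any query time, so F
  depends on the exposure history only through the metric's running max;
* interval probabilities in the likelihood are floored at 1e−12 before
  logs, 0·ln 0 is defined as 0, and an interval with observed deaths but
  exactly zero predicted probability yields −∞ (returned, not raised).

Trajectories are therefore independent of the output grid; the test suite
verifies |ΔS| < 1e−4 against a brute-force explicit-Euler oracle on 100
random study-realistic scenarios. The oracle runs at Δt = 2e−5 d because
forward Euler's own truncation error at coarser steps is comparable to the
agreement band at loss rates near 7 d⁻¹ — a finer oracle makes the
comparison a stricter check of the analytic solver.

## Calibration

Observed survivor counts are interval censored; the log-likelihood is the
multinomial form Σ (y_{i−1} − y_i) ln(S_{i−1} − S_i) with the censoring
convention S_{n+1} = 0, y_{n+1} = 0 (survivors at the last observation die
in (t_n, ∞)), summed over treatments. Calibration is two-step: least
squares of the survival curve against survivor fractions supplies starting
values, then Nelder–Mead maximises the likelihood in log-parameter space
(positivity by construction; invalid regions appear as the large penalty
1e12, never as silent clipping). Multi-start is seeded: the least-squares
solution, the user initial guess, optional warm starts (the pipeline feeds
single-set estimates into the combined-data calibration, which guarantees
the combined fit's joint likelihood is at least that of either single-set
solution), and log-normal perturbations with σ = 0.5.

The background hazard is fitted first from pooled controls by 1-D Brent
search on log h, bracketed at the moment estimator −ln(fraction
surviving)/T; the bracket keeps the search away from the floored-likelihood
plateau at implausibly large hazards. Zero observed control mortality puts
the estimate on the boundary h_b = 0, returned flagged. Toxicokinetic
parameters are fitted beforehand by pooled, equally-weighted least squares
on untransformed concentrations (additive measurement error assumed; no
per-dataset weighting, since nothing in the emulated design justifies one)
and held fixed in full-variant calibrations.

Confidence intervals are profile-likelihood based: one parameter walks a
multiplicative grid (factor 1.25, up to 60 steps per side) while the others
are re-optimised warm-started from the neighbouring grid point; the 95%
bound sits where the profile drops χ²₁(0.95)/2 = 1.9207 below the maximum
and is refined by log-space bisection. A side on which the profile never
drops is reported as None — "not determined" — which is the expected
outcome for, e.g., a threshold lying above everything the dose metric
reaches.

Model comparison mirrors the calibration-data question the study design
poses: each fitted cell (mechanism × dose metric × calibration set) is
evaluated on both data groups; the total likelihood adds the fitted group's
log-likelihood to the held-out group's, and the mean percentage error
(1/n) Σ |S_obs − S_model|/S_model · 100 gives the practitioner's view.

## Dose–response and recovery summaries

Daily LC50 values come from least squares of percent survival against
log10 concentration on the two-parameter log-logistic curve with top fixed
at 100% and bottom at 0%; confidence limits are asymptotic (t-quantile on
the fitted log10 LC50, hence asymmetric on the concentration scale), the
convention of standard dose–response software. Data entirely above or below
50% survival leave the midpoint unidentified and are flagged rather than
fitted to a pretence of precision. Note that with exact (noise-free) input
the asymptotic interval collapses onto the estimate.

The organism recovery time is the time from the start of a single defined
pulse (1 d by default) until the dose metric first falls to 5% of its
running maximum. For reduced metrics this is pulse_duration + ln(20)/k_d
exactly; for full metrics the damage keeps rising ~0.1–0.5 d into the
clean-water phase before its double-exponential decay, and both the peak
and the crossing are located on the closed form. Linearity makes the result
independent of pulse height (property-tested). Measuring from pulse start
is a package choice validated by reproducing the full grid of recovery
times from the corresponding k_d estimates; the origin is configurable.

## Synthetic data

The generator reproduces the emulated study's layout: two-pulse treatments
(1-d pulses at 28 nmol/mL — about the 1-d LC30 — with 2-d or 6-d recovery
gaps, 10 d total), a constant treatment at the pulsed treatments' measured
time-weighted average of 4.6 nmol/mL, a seven-concentration 4-d acute
series spanning 8.2–37.4 nmol/mL (geometric spacing, since the measured
series is not public), unexposed controls, and 1-d toxicokinetic exposures
at 8.7 nmol/mL with 5-d or 1-d depuration. Defaults: ten organisms per
beaker, seven replicate beakers per pulsed treatment, two per acute
concentration, daily observations.

Survivor counts are drawn by sequential conditional-binomial thinning,
y_i ~ Binomial(y_{i−1}, S_i/S_{i−1}) — the population-level distribution
implied by the multinomial likelihood with independent individuals, for SD
and IT alike — so generated data match the fitting model's statistical
structure exactly. Internal concentrations get unit-mean log-normal noise
with CV 0.15, the order of the analytical recovery spread of the assays
being emulated. What the generator deliberately omits: beaker-level
covariates (feeding, moulting), within-segment drift of measured
concentrations, and any correlation between beakers. Passing the recovery
and coverage tests therefore shows the estimator is consistent and the
intervals calibrated *under the model's own noise*, not that the model is
correct for real organisms.

## Problem sizes in the tests

Parameter-recovery and coverage checks run 15 replicate synthetic studies
per mechanism at 70 organisms per treatment (700 in total across the ten
treatments), with bias measured on the mean estimate and coverage pooled
over the three free parameters; the solver-oracle comparison uses 100
random scenarios. These sizes were chosen to pin the statistical properties
with comfortable margins while keeping the default suite quick to run.

## Known limitations

* The combined GUTS likelihood mixing SD and IT in one model is out of
  scope, as are time-varying background hazards, growth dilution,
  multi-compartment kinetics and sublethal endpoints.
* Simultaneous TK+TD joint fitting is not offered; toxicokinetics are
  always pre-calibrated, which propagates no TK uncertainty into the
  toxicodynamic intervals.
* The least-squares step weights all observation times equally; no
  replicate-beaker overdispersion is modelled.
* Profile bounds inherit the optimiser's tolerance; with nearly flat
  profiles the reported bound can wander within ~1% of the likelihood-exact
  position.
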