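# Methods

## Model

The package models radiation-induced blood–brain-barrier damage after
single-fraction, spatially confined brain irradiation with two coupled
empirical relations in dose `D` (Gy) and follow-up time `t` (weeks,
week 0 = irradiation day):

* onset of MRI contrast enhancement,
  `t_on(D) = max(0, t1 + t2 ln(D/Gy))` with `t2 < 0` — onset shortens
  logarithmically with dose and is clamped at 0 because a lesion cannot
  precede irradiation (the un-clamped line would go negative above
  `exp(t1/|t2|) ≈ 86.5 Gy` for the reference parameters);
* growth of the contrast-enhancing (CE) volume for `t ≥ t_on(D)`,
  `log10(V/µl) = a (D − D0) t^b` — linear in dose above the threshold
  dose `D0`, a power law in time.

Two sign/unit conventions are fixed by the package. First, the onset law
is written with `+ t2` and a negative `t2 = −12.5` weeks, the combination
that makes onset *decrease* with dose and puts the highest-dose onset at
0.975 weeks — the observed "one week". Second, volumes are in µl (= mm³):
with the reference coefficients the growth law then predicts terminal
lesions of roughly 45–75 µl, i.e. 10–15 % of the ~491 µl mouse brain,
which is the physically plausible scale (an ml-scale reading would exceed
the whole brain by two orders of magnitude). Evaluating the growth law
before the predicted onset is permitted but emits a `PreOnsetWarning`,
since the relation is only asserted from the onset onward.

Reference parameter sets: sensitive strain (C3H/He-like)
`a = 0.0155 Gy⁻¹`, `b = 0.40`, `D0 = 30 Gy`, `t1 = 55.75`,
`t2 = −12.5` weeks; resistant strain (C57BL/6-like) identical except
`b = 0.28`. The growth exponent is the only strain-specific parameter.

## Fitting protocol

**Onset.** `t1`, `t2` are obtained by unweighted ordinary least squares of
per-mouse onset week on `ln D` (closed form; one observation per animal,
not group means). At least three observations over at least two distinct
doses are required; a single dose level is a singular design. Validation
on a second cohort performs no refitting: R² is computed out-of-sample as
`1 − SSres/SStot` with predictions from the fixed parameters and `SStot`
around the validation cohort's own mean.

**Volume.** `a`, `b`, `D0` are estimated by nonlinear least squares of
`log10 V` (scipy `least_squares`, trust-region reflective) pooling all
post-onset, CE-positive points of the training strain. Fitting on the
log10 scale matches the model statement and makes the assumed noise
additive. Only positive volumes at scans at or after the observed onset
enter; pre-onset and zero readings are excluded and controls contribute
nothing. Because only three dose levels are typically available, `a` and
`D0` are weakly identified jointly; reproducibility is ensured by a
single deterministic start (`a = 0.01 Gy⁻¹`, `b = 0.5`,
`D0 = min dose − 10 Gy`) and box bounds `a ∈ (0, 1]`, `b ∈ (0, 2]`,
`D0 ∈ [0, min dose)`, with objective tolerance 1e-10. Non-convergence is
returned as a flagged failure, never silently. The cross-strain transfer
is the same operation with `b` free and `a`, `D0` fixed at the training
estimates.

R² is always `1 − SSres/SStot` on the fitted scale and is undefined (an
error) when the observations have zero variance.

## Synthetic cohorts

The generator emulates the study design the model was built for: two
strains, three irradiated dose levels each plus sham controls (3 + 1
animals per group, 10 per strain), a pre-irradiation scan at week −1,
biweekly scans starting in week 1 or 2 (drawn per mouse), the interval
widening to 5 weeks after week 13, and a 26-week follow-up horizon with a
terminal scan at the horizon when the grid overshoots it.

Per scan, the measured volume is the model prediction times `10^ε` with
`ε ~ N(0, σ²)`, `σ = sigma_log10 = 0.1` by default — a multiplicative
lognormal error chosen to be conjugate to the log-scale fit; no noise
model is asserted by the underlying data, so this is the generator's own
assumption. Volumes below the 1 µl detection threshold read 0 (the MRI
protocol's true contouring limit is unknown; 1 µl is a configuration
knob). The observed onset is the first scan with a detectable volume —
a right-shifted, grid-discretised version of the latent onset, which is
infinite for controls and for doses at or below `D0`. Volumes are capped
at the 491 µl whole-brain volume with a warning.

Sacrifice for health deterioration is simplified to a volume rule: the
first scan at or above the 60 µl sacrifice threshold is the terminal
diagnostic scan (event = 1); otherwise the animal is censored at the
horizon. The 60 µl default calibrates the sensitive strain's highest-dose
group to leave the experiment around weeks 9–10 (~63–70 days), matching
the observed scale; it is a simplification, not a physiological claim —
under it the resistant strain's highest-dose group exits around weeks
14–18, later than the ~11 weeks observed in real animals whose composite
health score also reflected weight loss and behaviour.

Randomness: one integer seed; each mouse gets a sub-stream derived from
(seed, CRC32 of its id), so enlarging a cohort never reshuffles the
trajectories of existing animals.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: there are no animal-level random effects (every
mouse of a group follows the same latent curve), no volume regression
such as the mild late recovery seen at the resistant strain's lowest dose
(the growth law is monotone and cannot express it), no contralateral or
T2-weighted signal, and no health-score dynamics. One visible consequence
is that fitted R² on synthetic cohorts concentrates near 0.95, higher
than the 0.76–0.80 regime typical of real longitudinal volume data.

## Survival

Kaplan–Meier estimation and the two-group Mantel–Haenszel log-rank test
(1 df chi-square, ties pooled at each distinct event time with
hypergeometric variance, censoring at an event time counted after the
event) are delegated to `lifelines`; the test suite cross-checks both
against an independent brute-force risk-table oracle on small cohorts.
The statistic is undefined (an error) when neither group has events.

## Problem sizes and checks

The test suite runs entirely on generated data: single-mouse and 20-mouse
cohorts, noise-free closure checks (generate → fit must return the
generating parameters to 1e-3 relative or better; onsets to within one
biweekly scan interval, the resolution limit imposed by the grid), a
100-replicate Monte Carlo at `sigma_log10 = 0.1` establishing that the
median recovered exponent stays within ±0.05 and the median growth-rate
coefficient within ±20 %, and survival comparisons against the
brute-force oracle on all-random cohorts of up to 10 animals.
`scripts/acceptance.py` re-runs the full pipeline on one default cohort
per invocation and writes every computed quantity as JSON.

## Limitations

The model is empirical: it encodes no mechanism, no spatial dose
distribution, no relative biological effectiveness, and is calibrated on
three dose levels per strain — extrapolation beyond ~40–85 Gy, and
especially below the threshold dose, is unsupported. Onset observations
inherit the scan-grid discretisation; with biweekly imaging the onset
parameters can only be recovered to within one interval. The
volume-threshold sacrifice rule orders strains correctly but compresses
the resistant strain's survival less than a composite health score would.
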