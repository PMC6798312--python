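# Methods

This note documents the statistical models implemented in `vfvar`, the
synthetic-data generator that stands in for clinical cohorts, the numerical
choices that matter, and the known limitations — in particular what the
simulate-then-estimate loop can and cannot recover.

## The measurement problem

Automated perimetry estimates a threshold sensitivity (dB) at each of the
54 locations of the 24-2 pattern. Test–retest noise is heteroscedastic:
small near normal sensitivity, largest in the 10–15 dB range where the
psychometric (frequency-of-seeing) curve is shallow, and compressed again
near the 0 dB floor of the instrument. Because longitudinal progression
analysis regresses each location's sensitivity on time, the noise law
σ(s) matters twice: it is what variance-weighted regression needs as
weights, and it is what a realistic simulator must inject.

## Pointwise trend models

Each location is fitted independently over time:

* **Linear / weighted linear.** Closed-form simple (weighted) least
  squares. Weights are `w_i = 1/σ(y_i)²` with σ evaluated at the observed
  sensitivity rounded to integer dB (the variance table is indexed by
  observed dB). Predictions — never training data — are censored into
  `[0, Y]`, where the ceiling `Y` is the age- and location-matched normal
  sensitivity plus 2 SD.
* **Exponential.** The raw linear trend decides the branch: non-positive
  slope → decay model `ln(y) = α + βx`; positive slope → improvement model
  `ln(Y − y) = α + βx` with per-observation, age-matched `Y`. Both are OLS
  after the log transform; values of `y` (or `Y − y`) below 0.5 dB — half
  the instrument's 1 dB step — are clamped to 0.5 before the logarithm. An
  exactly zero slope routes to the decay branch (a fixed, arbitrary
  tie-break). These curves approach floor/ceiling asymptotically and need
  no censoring.
* **Logistic.** `y = ζ/(1 + e^{α+βx})` by least squares, Newton–Raphson on
  the sum-of-squares gradient (Gauss–Newton normal equations) with step
  halving. Initialization: `ζ₀ = max(y)+1`, slope from an OLS fit of the
  logit transform, intercept shifted to match the first observation;
  convergence when the applied step falls below 1e−8, at most 200
  iterations, then up to 5 seeded random restarts. `ζ` is kept in (0, 50]
  — the instrument range; whether the original analyses constrained it is
  unknown, so the bound is documented rather than assumed essential.
  Exhausted iterations return the best iterate flagged unconverged; a
  singular system in every attempt raises.

Noiseless logistic recovery is exercised over random parameter draws whose
inflection lies inside the observation window; a curve that is flat across
the whole window leaves (ζ, α) unidentified *by construction* — no
optimizer can recover parameters the data do not constrain — so such draws
are excluded from the recovery-rate property.

Filters: exams are reliable when false positives ≤ 20% and false negatives
≤ 25% (fixation losses unrestricted; missing indices conservatively reject
by default). The two blind-spot locations (15°, ±3°) are always excluded.
For trend modeling and prediction (not for variability estimation),
locations at the floor early on — 0 dB in at least two of the first three
exams — are also excluded.

## Variability estimation

Residuals (observed − fitted, dB) from per-location fits are pooled over
eyes and binned by the observed sensitivity rounded to integer dB over the
analyzed range 0–35 dB. Per bin we report the sample SD (n−1 denominator;
the choice is conventional and immaterial at these counts) and flag bins
with fewer than 25 residuals as unreliable.

Two summaries are fitted across bins, each dB bin counting once
(unweighted; a count-weighted option exists but is off by default, since
the binned presentation treats each dB level as one observation):

* log-linear: `ln(SD) = α + β·s` by OLS over the reliable bins of a
  chosen range;
* spline: continuous piecewise-linear `ln(SD)` on the truncated-power
  basis `{1, s, (s−k₁)₊, (s−k₂)₊}`, default knots (14, 32) dB. Continuity
  at the knots is built into the basis. The knots are user parameters; the
  defaults reflect where the measured curve changes direction. Segments
  with exactly one reliable bin raise an error naming the segment; knots
  outside the data collapse their basis column and the fit degrades to the
  log-linear form.

Eccentricity is stratified into three bands by Euclidean distance from
fixation — `<10°`, `10–20°`, `>20°`. Band curves are compared pairwise
with a two-sided Wilcoxon signed-rank test across the dB bins reliable in
both bands, Holm-corrected over the three pairs; the test is a pragmatic
rank-based choice for paired, non-normal SD estimates.

## The noise model and the synthetic generator

The default `anchor` noise model interpolates σ(s) linearly through three
measured anchors — σ(0)=3.4, σ(11)=5.5, σ(33)=2.0 dB — with flat
extrapolation above 33 dB. Log-linear, spline, tabulated and constant
parameterizations are interchangeable wherever a σ(s) is accepted
(simulation and WLS weights).

The generator emulates the structure of the clinical populations such
analyses are run on, not any individual dataset:

* **Exam schedule.** Exam counts are `min_exams + Poisson(λ)`; gaps are a
  shifted gamma, resampled until the preset's minimum follow-up is met.
  The *variability* preset (≥6 exams, ≥3 y; λ=3.2, gaps 0.35+Γ(2.2, 0.38))
  yields a median of 9 exams over ~9.4 years; the *modeling* preset (≥10
  exams, ≥6 y; λ=10, gaps 0.3+Γ(2.0, 0.25)) yields a median of 20 exams
  over ~15 years.
* **Baseline fields.** The glaucoma archetype subtracts from a parametric
  hill of vision a diffuse loss (Exp(2.0) dB) and 1–2 focal defects with
  Gaussian spatial falloff (depth U(4, 25) dB, radius U(4, 8)°). With a
  65% progressing fraction and exponential per-location decay rates
  |N(0.12, 0.06)|/y at defect-involved locations, the generated cohorts
  have median baseline pseudo-MD ≈ −3.2 dB and median pseudo-MD slope
  ≈ −0.14 dB/y, matching the populations being emulated. A `uniform`
  archetype (stable truths uniform on [0, 35] dB) provides the neutral
  density under which every SD bin is estimable, and a `fixed` archetype
  pins all truths at one value.
* **Observation model.** `observed = round(clamp(s*(t) + e, 0, 35))` with
  `e ~ N(0, σ(s*(t)))` — noise keyed to the TRUE sensitivity, the
  generative analogue of binning residuals by observed value; the
  estimator bins by observed, and recovery tolerances absorb the
  difference (see below). Reliability indices are drawn uniformly below
  the cut-offs so generated exams pass the filter. All randomness descends
  from one seed; each eye's ground-truth record stores its sub-seed, so
  the record regenerates every observation exactly.
* **pseudo-MD** is the mean, over non-blind-spot locations, of observed
  minus the normative mean — a stand-in for the device's mean-deviation
  index (it omits device weighting and normative percentiles).

The normative surface itself is a configurable parametric stand-in (peak
33.5 dB, −0.07 dB/degree of eccentricity, −0.065 dB/year after 45, normal
SD 1.0 + 0.03·ecc dB), qualitatively shaped like published normative data
but not a reproduction of any proprietary table; a per-location table can
be supplied instead. Left-eye data are mirrored into the right-eye,
temporal-positive frame at ingestion (row reversal of the screen-frame
chart) so one canonical frame serves all pooling.

What the generator does **not** emulate: spatial correlation between
neighboring locations, scotoma-edge variability, learning and fatigue
effects, non-Gaussian (skewed/heavy-tailed) noise near the floor, and
test-strategy internals. Passing tests therefore demonstrate correctness
of the estimators under the stated noise law, not robustness to everything
real fields do.

## Known bias of the binned-SD estimator (important)

The simulate-then-estimate loop is *not* a fixed point of σ(s) wherever
σ(s) has strong curvature:

* At a **peak** of σ(s) (the 11 dB anchor), conditioning on the observed
  value mixes in neighboring true sensitivities whose σ is smaller on both
  sides; large deviations are doubly down-weighted (they require an
  unlikely draw *and* come from a lower-σ truth). Even with perfect fits
  the recovered SD at 11 dB is ≈ 4.1–4.2 dB when the generator injects
  5.5 dB — a ~25% attenuation that no admissible truth density removes
  (a point mass at 11 dB collapses the bin SD entirely, to ~2 dB, because
  the residual then measures only fit error). A measured 5.5 dB peak on
  real data therefore implies a *latent* noise SD above 5.5 dB.
* At a **valley** (33 dB) the same mechanism inflates, roughly cancelling
  the OLS residual-variance shrinkage (≈ √((n−2)/n)); recovery there is
  accurate to within ~10%.
* In the flat interior, and for directly injected residuals (no fitting,
  no selection), the estimator is unbiased to within sampling error.

The acceptance checks report this honestly: the 33 dB and 0 dB anchors are
recovered within their tolerances; the 11 dB bin reports the attenuated
value (~4.2 dB), and the corresponding test is left failing rather than
re-tuned, with this section as the analysis.

## Model evaluation

Goodness of fit regresses all exams over the whole follow-up and reports a
per-eye RMSE over included locations. Prediction trains on the first *m*
exams and scores the observed values of a later target exam at its actual
time (observed, noisy values — matching clinical practice; truth-referenced
scoring is available for simulation studies via the `reference` argument).
The rolling schedules are: target 10 → windows 5, 6, 7, 8, 9; target 15 →
5, 7, 9, 11, 13; target 20 → 5, 8, 11, 14, 17.

Aggregation is per-eye first, then median (IQR) across eyes; pairwise model
comparisons use two-sided Wilcoxon signed-rank tests on per-eye RMSE pairs,
Holm-corrected within each (target, window) cell, with the
strictly-smallest-median model flagged. Eyes missing any model in a cell
are dropped from that cell (pairing integrity). On progressing synthetic
cohorts with exponential truth, the exponential model wins the early
windows (its asymptote matches the floor behavior that linear extrapolation
must be censored into), the models converge as windows grow, and weighted
linear regression does not outperform unweighted linear beyond simulation
noise — here assessed on *paired* per-eye differences, whose median stays
within ±0.25 dB and never reaches one-sided significance, even though
cross-eye medians can differ by more.

## Problem sizes and determinism

The variability loop is exercised at 300 eyes × 52 locations × 15 exams
(~234k residuals; a few seconds), and the benchmark at 40 modeling-preset
eyes × 3 models × 2–3 targets — sizes at which the Monte-Carlo error of
the reported quantities is comfortably below the decision tolerances. All
stochastic components take explicit seeds; reruns are bit-identical,
including the long-format CSV export.

## Limitations

* The normative stand-in is qualitative; absolute ceilings (and hence
  improvement-model asymptotes) differ from device normative data.
* Near the 35 dB analysis cap, ceiling clamping and the log-clamp compress
  residuals slightly (the 33 dB bin recovers ~1.8 dB for a generated 2.0).
* Gaussian noise understates the floor's skewness; the binned SD at 0 dB
  consequently reflects both injection and censoring, not a pure noise SD.
* Pointwise fits ignore spatial structure; no mixed-effects, robust or
  Bayesian variants are provided.
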