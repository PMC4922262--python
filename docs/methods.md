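# Methods

This note documents the models, estimators, numerical choices and known
limitations of `respirotools`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Measurement model

Intermittent-flow respirometry alternates sealed measurement periods with
flush periods that restore full air saturation. The canonical cycle is
8 min — 300 s measure, 180 s flush — with dissolved O₂ sampled at 0.5 Hz.
Within a sealed window the chamber concentration obeys

    dC/dt = -(m(t) · M + B(t)) / (3600 · V_resp)

where m is the mass-specific uptake (mg O₂ kg⁻¹ h⁻¹), M the fish mass (kg),
B a whole-chamber background rate (mg O₂ h⁻¹) and V_resp the chamber volume
minus the fish volume (L). The engine estimates m per window as the
ordinary-least-squares slope S of C against time, converted by
M&#775;O₂ = S·V_resp/M (× 3600 for hourly units), minus background interpolated
linearly between an empty-chamber rate measured before and one measured
after the trial. When m varies within a window (early post-exercise decay),
the OLS slope estimates approximately the window mean of m; the residual
discrepancy is second-order in (window / decay time constant) and is below
0.1% for the default 60 s window against a 900 s decay.

Conventions: time is 0-based seconds from trial start; all windows are
half-open [start, end); trace CSVs are comma-separated, dot-decimal, UTF-8
with a mandatory header (no dialect sniffing). The 100% air-saturation
concentration is a configuration input (default 6.2 mg/L, warm seawater at
~28.5 °C and salinity ~35) rather than an internal solubility model — the
salinity/pressure conventions of any given lab should not be hidden inside
the package. Fish volume defaults to mass × 1.0 L/kg (fish ≈ neutrally
buoyant) and is overridable where displacement was measured.

## Estimators

* **Window segmentation** — contiguous runs of `measure`-labelled samples
  (labels taken from the file or derived from the cycle schedule); an
  optional lead trim discards mixing-transient seconds at each window
  start (default 0); partial trailing windows are kept only if ≥ 60 s.
* **MMR, swim protocol** — the M&#775;O₂ at the highest speed at which the fish
  completed at least one full cycle; among that speed's completed-cycle
  windows the *maximum* is taken (the singular "the M&#775;O₂ at the maximal
  speed" reading; the mean is available by option).
* **MMR, chase/circle** — steepest 1-min window by sliding-window OLS at a
  2 s stride (the sampling interval, i.e. exhaustive at sample resolution),
  over the first 300 s (chase) or a configurable 300–420 s (circle); ties
  break to the earliest start.
* **SMR, lowest fraction** — mean of the k = ⌈0.10·n⌉ smallest window
  values starting at or after the recovery cutoff (default 6 h, the lower
  bound of the 6–12 h settling period). At least 10 eligible windows are
  required so the "lowest 10%" is an average, not a single noisy minimum.
  This order-statistic estimator is biased low under sensor noise; the
  trend is asserted in the test suite and should be kept in mind when
  comparing labs with different optode noise.
* **SMR, extrapolated** — nonlinear least squares of M&#775;O₂(U) = a + b·U^c
  (c ≥ 1) over the swim trial's speed-window pairs; a estimates SMR. Needs
  ≥ 3 distinct speeds.
* **U_crit** — Brett's interpolation U + U_i·(t/t_i) with t the time swum
  into the failed increment (t_i default 1440 s). Both absolute (cm/s) and
  length-relative (BL/s) forms are computed.
* **Solid blocking** — ε = τ₀·λ·(A_fish/A_tunnel)^{3/2} with τ₀ = 0.8
  (streamlined body) and λ a fineness-type shape factor (helper: standard
  length over equivalent circular diameter of the max cross-section);
  corrected speed = speed·(1+ε), with a warning when ε > 0.05 (boundary
  inclusive — exactly 5% does not warn).
* **Diagnostics** — every window carries r², a background fraction and its
  minimum air-saturation fraction; windows below 80% saturation are flagged
  (hypoxia risks a stress response that contaminates M&#775;O₂), never dropped
  silently. Background-corrected uptake below zero is clamped to 0 and
  flagged rather than raised: with low night-time SMR and a noisy
  background estimate the difference can legitimately cross zero. r² is
  reported but not used as a rejection filter by default (an optional
  minimum can be configured); full-window OLS is always used rather than
  hand-selected sub-regions, which keeps the estimator reproducible.

## Synthetic-data generator

The simulator emulates the measurement chain for three protocols with
known ground truth per fish (SMR, MMR, U_crit, EPOC time constant). O₂
curves are integrated analytically per segment, so noise-free traces
satisfy mass balance to machine precision; Gaussian i.i.d. sensor noise
(default sd 0.002 mg/L, the sample-to-sample precision of a well-calibrated
optical O₂ spot) is added on top. Flushes are instantaneous by default
(exactly restoring saturation) or first-order exponential by option.

* **Speed–uptake model (swim)** — m(U) = SMR + (MMR−SMR)·((U−U₀)/(U_crit−U₀))^c
  with U₀ the habituation speed and c default 2 (drag-power heritage),
  clamped at MMR. The trial habituates (default 4 h) at 0.5 BL/s, ramps
  240 s to 4 BL/s, then climbs 0.5 BL/s increments of three 8-min cycles;
  it terminates (U_crit − U_last)/U_i · t_i seconds into the increment
  containing the true U_crit, so Brett's formula applied to the recorded
  fatigue time recovers U_crit exactly.
* **EPOC (chase, circle recovery)** — a single exponential,
  m(t) = SMR + A·e^{−t/τ}, the simplest decay consistent with repayment of
  an oxygen debt; τ defaults to 900 s (a fast repayment component with a
  ~10-min half-life, typical of small active reef fish). The chase trace
  starts after a handling delay (default 10 s, the protocol's stated
  ceiling). The circle trial ramps m linearly over 60 s to its plateau and
  measures continuously (no flush) for a 300–420 s exercise bout.
* **Method attenuation** — each short protocol expresses only a fraction a
  of the true span as peak excess: A = a·(MMR−SMR). Defaults a_chase = 0.85
  and a_circle = 0.77 are calibrated so that cohort-level model-predicted
  MMR differences land near +20% (swim vs chase) and +25% (swim vs circle)
  for the default four-species design: with window-mean factor
  f = e^{−delay/τ}·(τ/60)(1−e^{−60/τ}) ≈ 0.957, pooled species means
  (m&#772; = 1503, s&#772; = 189, span&#772; = 1314 mg O₂ kg⁻¹ h⁻¹) give
  a_chase = (m&#772;/1.2 − s&#772;)/(f·span&#772;) ≈ 0.85 and
  a_circle = (m&#772;/1.25 − s&#772;)/span&#772; ≈ 0.77 (the circle plateau is measured
  without window-mean loss). These are calibration targets of the
  generative design, not measured biology.
* **Spontaneous activity** — a per-cycle half-normal increment with scale
  5% of SMR, so resting traces settle to SMR plus small positive activity
  noise, as real post-recovery records do.
* **Cohorts** — between-fish parameters are log-normal (positivity);
  the default four-species design (two body-caudal-fin, two
  median-paired-fin swimmers; n = 5, 11, 11, 10) takes species means from
  the published group means of the study system this package models and
  between-fish CVs from their SEMs (CV = SEM·√n / mean). Each fish runs
  the three protocols in randomized order (repeated measures); trials can
  be masked to emulate incomplete designs. All randomness flows from
  explicit integer seeds.
* **Summary-level cohorts** — for auditing the statistical stage at scale,
  `simulate_method_effect_cohort` draws fish × method summary values
  directly from the multiplicative model value = species mean · fish
  effect · method ratio · noise, which on the log scale is exactly the
  random-intercept model the comparison stage fits, making true method
  log-ratios available for coverage checks at a fraction of the cost of
  trace-level simulation.

What the generator does **not** emulate: chamber mixing dynamics and
washout kinetics beyond the flush contract, temperature drift (temperature
is a constant column), gait transitions, bi-exponential EPOC, diel activity
rhythms, and the vortex flow field of the circular chamber (whose swimming
speed is treated as unmeasurable, as in practice). Passing recovery tests
therefore demonstrates correctness of the estimation chain under the stated
generative assumptions, not robustness to every artefact of real traces.

## Statistical stage

MMR and SMR comparisons use a linear mixed model (statsmodels `MixedLM`,
REML) with method and species as fixed factors and fish identity as a
random intercept; the method × species interaction is tested first by a
Wald F and removed when non-significant at α = 0.05. Denominator degrees of
freedom use a containment-style approximation, n_obs − rank(X) −
(n_groups − 1); the exact df convention is a configuration-level choice and
only affects borderline p-values. All-pairs method contrasts are built from
species-balanced prediction rows; the default multiplicity adjustment is
single-step multivariate-normal (max-|Z|), evaluated by sampling the
contrast distribution through a rank-revealing factor with a fixed internal
seed (the contrast covariance is singular by construction — k pairwise
contrasts from k−1 free coefficients); Holm and unadjusted options exist.
With fewer than two fish carrying repeated measures the model falls back to
fixed-effects OLS with an explicit note. Percent differences are
100·(pred_A − pred_B)/pred_B on the raw scale or 100·(e^{Δ}−1) on the log
scale, with per-species ranges.

A note on scales: the generative method effect is multiplicative, so on the
raw scale its absolute size grows with a species' span and a raw-scale
method × species interaction is real and detectable at low noise; on the
log scale the model is exactly additive. The coverage audit therefore runs
on the log scale, while headline percent differences follow the
conventional raw-scale fit.

U_crit (one value per fish) uses a fixed-effects linear model with species
nested in swim mode (sequential sums of squares: mode, then species within
mode), Tukey HSD pairwise species comparisons, and a compact letter display
computed from maximal cliques of the non-significant-pair graph.

## Validation studies and problem sizes

The acceptance script and `tests/test_acceptance.py` run, at sizes chosen
to keep a full desk run in minutes:

1. noise-free per-window recovery (≤ 10⁻⁶ relative) and steepest-window
   agreement with exhaustive enumeration on 1000 random traces;
2. a 50-fish trace-level cohort under default noise — median |relative
   error| ≤ 5% for lowest-decile SMR and swim MMR, and chase/circle peak
   excess within 5% of its attenuated target;
3. Brett-interpolation boundary identities and arithmetic;
4. 200 summary-level cohorts (n = 20 per species) with generative
   swim:chase:circle ratios 1.0 : 0.833 : 0.8 — contrast-CI coverage of
   the true log-ratios ≥ 90% and correct cohort-mean ordering in ≥ 95% of
   replicates;
5. the solid-blocking bound ε ≤ 0.05 for fish geometries far smaller than
   a 7 × 7 cm working section.

## Known limitations

* The chase MMR estimator inherits a deterministic low bias of a few
  percent from averaging a decaying EPOC curve over a 1-min window (plus
  the handling delay); this mirrors the real protocol's weakness and is
  why the simulator's attenuation calibration folds the window factor in.
* The lowest-decile SMR estimator is noise-biased low; at the default
  optode noise the bias is well under 1% but grows with noise_sd.
* Background correction interpolates linearly per window between one pre-
  and one post-trial rate; labs that measure background differently should
  construct `BackgroundModel` accordingly.
* No closed-system (non-intermittent) mode, no chamber-mixing
  deconvolution, no gait-transition speeds, and no EPOC-magnitude (area
  under the recovery curve) integration — only the peak-window estimate.
* Proprietary logger formats are not ingested; convert to the documented
  CSV first.
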