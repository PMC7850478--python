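# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of the package.  Everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`.

## Data model

An experiment is an *event table*: one row per event per growth channel,
`channel_id,time_h,event` with events `division`, `death`,
`end_of_observation`.  Time is hours from the start of observation.  Per
channel, events are strictly increasing in time and exactly one terminal
event (death or end-of-observation) comes last; the terminal event is
explicit so that truncated files fail loudly.  Because the mother machine
retains only the closed-end cell after each division, consecutive complete
cycles in a channel form a mother-daughter chain by construction.

Complete cell cycles span consecutive division events.  The first segment
(birth unobserved) and the last segment (division censored by death or the
window end) are always excluded.  A channel with d division events
therefore yields d − 1 complete cycles and d − 2 consecutive-generation
pairs.  Note the lineage filter at ≥ 4 divisions guarantees two — not
three — mother-daughter pairs per lineage under this bookkeeping; the
per-lineage correlation therefore requires ≥ 3 pairs explicitly and
excludes (with a reported count) lineages that hold fewer.

## Generation-time mixture

Density and survival function of the mixed shifted exponential are closed
forms (see README).  Properties of the reference parameter point
(λ₁ = 0.571 h⁻¹, λ₂ = 0.134 h⁻¹, τ₀ = 8.375 h, a = 0.060):
g(τ₀) = (1−a)λ₁ + aλ₂ = 0.5448 h⁻¹; mean τ₀ + (1−a)/λ₁ + a/λ₂ = 10.469 h;
B(14.0) = 0.0661.  The smallest τ on a 0.01 h grid with B(τ) ≤ 0.06 is
14.26 h; the conventional cutoff used for classification is nevertheless
14.0 h, kept as the default because it is the established constant for this
system even though it is not exactly derivable from the parameter point
(B(14.0) = 0.066 > 0.06).

**Two-stage fit.**  Stage 1 fits a free-amplitude exponential A·e^{−λτ} by
Levenberg–Marquardt (linear survival scale, log-linear initialisation) on a
fast window (10–12 h, closed interval) and a slow window (25–42 h); stage 2
fixes both decay constants and fits (a, τ₀) over the full curve.  The free
amplitude is required because a sub-window of a survival curve is not
anchored at 1.  This recipe is *descriptive*: on a noiseless model curve
the slow component contributes 11–17% of the survival mass inside the fast
window, so the recovered λ₁ is ≈ 0.50 h⁻¹ against the generative 0.571 h⁻¹,
while the stage-2 curve still tracks the input with mean squared residual
≈ 2×10⁻⁵ (maximum pointwise deviation ≈ 0.03).  When both windows see the
same decay (single-component data) the fit degrades gracefully to the
single-shifted-exponential fit and is tagged as such.

**EM maximum-likelihood fit.**  τ̂₀ is the sample minimum (its bias
1/(n·g(τ₀)) ≈ 3×10⁻⁴ h at n = 6,033 is negligible); EM then fits the
two-component exponential mixture on the excesses.  EM agrees with direct
likelihood maximisation to machine precision (checked against Nelder–Mead
on replicate simulations).  Convergence uses a relative tolerance plus an
absolute log-likelihood floor of 10⁻⁵ per iteration: near an
unidentifiable merged optimum EM creeps indefinitely at O(10⁻⁵) per step,
and such gains cannot move the parameters materially.  Degeneracy is
flagged by boundary weight, merged decay constants, or a two-component
log-likelihood within 2 units of the closed-form single-exponential
maximum.  Standard errors come from the observed information
(finite-difference Hessian).  Monte-Carlo SDs at n = 6,033 (20 replicates):
λ₁ 0.011, λ₂ 0.012, τ₀ 3×10⁻⁴, a 0.012.  The slow fraction a is the
weakest-identified parameter: single-experiment deviations of ±0.02–0.03
from 0.060 are ordinary.

## Synthetic lineage generator

The generator's defaults are the study conditions: 523 channels, a 168 h
(7-day) window sampled at Δt = 10 min, the reference mixture marginal, a
constant baseline death hazard of 2.239×10⁻³ h⁻¹, and the calibrated
copula parameters below.

**Heritability mechanism.**  The observations constrain the marginal and
two correlation targets but not the generative law; the package chooses a
Gaussian copula with a two-timescale latent.  Channel i draws a persistent
component u_i ~ N(0, c); generation k adds a stationary AR(1) innovation of
variance 1 − c and coefficient φ, so the latent score z_k is standard
normal with lag-k autocorrelation c + (1−c)φᵏ, and τ_k = G⁻¹(Φ(z_k))
preserves the mixture marginal exactly.  Two timescales are necessary: a
single AR(1) hitting lag-1 = 0.62 decays to ~0.008 by lag 10, and a
two-state Markov switch with this marginal cannot exceed a lag-1
correlation of ~0.23 (variance decomposition: the between-state variance is
a(1−a)(1/λ₂−1/λ₁)² ≈ 2.1 h² of a total ≈ 9.4 h²).  Whether the real
slow-cycling state is discrete or continuous is open; the generator makes
the continuous-latent choice and this is a modelling commitment, not a
finding.

**Calibration.**  `calibrate_copula` first inverts the attenuation of the
quantile transform — the Pearson correlation of (τ₁, τ₂) under latent
correlation ρ is computed by two-dimensional Gauss–Hermite quadrature
(80 nodes) and inverted by bisection — and solves the closed form for
(c, φ).  Pooled pairs from a fixed window over-represent fast lineages, so
the semi-analytic solution is then corrected iteratively against
simulations (2,000 channels; eight replicate simulations per iteration,
full-gain steps first, damped 0.6 afterwards since the response gain
exceeds one; the final parameters come from the last correction without a
further accept/reject, avoiding selection bias).  Calibrated defaults for
targets (0.62, 0.20): c = 0.3748, φ = 0.5835.  Single-experiment
estimates at 2,000 channels scatter with SD ≈ 0.008 (lag 1) and ≈ 0.013
(lag 10) around the calibrated centre — the lineage-persistent latent
clusters pairs within channels, so the lag-10 coefficient has far fewer
effective degrees of freedom than its ~10⁴ pairs suggest.

**Observation model.**  True division times accumulate the copula τ's;
recorded division and death times snap to the end of their 10-min frame.
Death occurs per frame with probability 1 − exp(−h·Δt); a death pre-empts
a division in the same frame.  During a drug phase the hazard switches,
after a configurable onset delay (default 50 h — the drug blocks
replication and kills only indirectly), to a state-dependent rate: 0.02 h⁻¹
for cells whose current generation time is ≤ 14 h, 0.002 h⁻¹ otherwise.
These drug-phase defaults are qualitative (endurance period, then sharp
decay of the fast stratum; shallow decay of the slow stratum), not fitted.

**What the generator does not emulate.**  (i) The marginal of complete
cycles *extracted from a fixed window* is not exactly the mixture: cycles
overlapping the window boundaries are excluded, under-sampling long
generation times, and slow lineages contribute fewer cycles each.  At the
default window this depresses the recovered slow fraction (window-extracted
MLE â ≈ 0.03 against the generative 0.060) — an inspection bias shared, in
principle, by any fixed-window experiment.  The distribution-equality
invariant therefore applies to the generator's per-generation stream
(`sample_correlated_taus`), not to window-extracted cycles.  (ii) No
division-rate slowdown during drug exposure (the real drug inhibits
cycling before killing).  (iii) No cell-size, fluorescence, or
within-channel crowding effects.  Passing tests demonstrate the statistical
machinery, not biological fidelity beyond the calibrated moments.

## Growth and correlation statistics

The division curve is the running sum of D(t)/N(t) per frame (divisions
among lineages alive at the frame start over that count).  The death rate
is the negative OLS slope of log surviving fraction over positive-survival
frames, matching the straight-line presentation of survival on a log axis;
lineages alive at the end are censored.  Its standard error is the Poisson
count error rate/√(deaths) — the survival points are serially dependent,
so a regression SE would be spuriously small.  Survival-curve point errors
are binomial √(S(1−S)/N₀); all lineages are tracked from t = 0, so no
interval-censoring machinery is needed.  Correlation SEs use the Fisher-z
form (1−r²)/√(n−3), applied at the rank scale for Spearman.  The
one-pair-per-lineage resampler draws one uniformly chosen mother-daughter
pair per retained lineage, 1,000 times by default, and reports the mean and
SD across resamples.

## Correlation-dimension analysis

Embedding follows the first-m-entries rule: lineage j with ≥ m complete
cycles becomes the vector (τ₁, …, τ_m).  This treats each surviving lineage
as a fragment of one hypothetical long trajectory — an ergodicity
assumption that conflates across-lineage and along-lineage variability and
is adopted deliberately, as is conventional for ensembles of short series.
The correlation integral uses the literal 1/N² ordered-pair normalisation
(maximum 1 − 1/N), Euclidean distance by default (max-norm available), an
inclusive Heaviside (a pair exactly at distance r counts), and a grid of
300 logarithmically spaced radii between the 1st and 99th percentiles of
pairwise distances.  The dimension estimate is the maximum slope of a
moving 5-point OLS regression on the log-log curve, restricted to the
scaling region: radii resolved by ≥ 50 unordered pairs (counting noise)
and with C ≤ 0.2·(1 − 1/N), because near saturation the integral steepens
for purely geometric reasons (distance concentration) and its slope no
longer measures a dimension.  So restricted, the estimator reproduces
known benchmarks: ≈ 1 for uniform scalars at N = 2,000, and a plateau at
≈ 2.0–2.4 for the chaotic-flow ensemble below.  With N ≈ 300 lineages,
estimates above ~2·log₁₀N ≈ 5 are unreliable; `GPResult` reports this
guardrail as a caveat without applying it.

**Comparator ensembles.**  The stochastic reference draws i.i.d. series
from a shifted gamma (shape 2, scale 1 h, shift 8.375 h — matching the
generation-time location and spread).  The deterministic reference samples
the x-coordinate of Rössler-flow trajectories (a = b = 0.2, c = 5.7;
fixed-step RK4, h = 0.02; 100 time units of transient; samples every 0.5
time units) from random initial conditions, rescaled affinely into the
8–40 h generation-time range.  A flow is used rather than a strongly
chaotic map: with a Lyapunov time shorter than the embedding window,
exponential stretching pushes the scaling region below what a few hundred
points can resolve, and the saturation signature of determinism is masked
by finite-sample steepening (measured: global log-log slopes for a Hénon
ensemble creep from 1.2 at m = 2 to ≈ 1.9 at m = 9 even at N = 1,500).
The Rössler ensemble sampled at half a time unit keeps divergence across a
12-point window mild and plateaus cleanly near its attractor dimension.
The saturation check compares the mean estimate over m = 6..9 with the
mean over m = 3..5 (plateau change < 0.5); single-m estimates carry ±0.25
of noise at N ≈ 300, so max-minus-min comparisons over-trigger.

Recorded generation times sit on the 10-min frame grid; for
correlation-integral analysis of such quantised series the analysis
scripts dither each value by ± half a frame (seeded), the standard remedy
for lattice-degenerate pairwise distances.

## Drug-response analysis

Events at exactly the exposure onset belong to the post phase (pre-window
is half-open [0, t_exp)).  Post-phase tables keep only channels alive and
under observation at onset.  Stratified survival is normalised per stratum
at the onset, on a frame grid measured from the onset, with binomial
errors; the size-weighted average of stratum curves reproduces the pooled
curve identically.  Classification uses the division-count threshold
k\* = floor(window/τ_c) + 1 for non-integer ratios (96/14 → 7); for an
exact integer ratio m the threshold is m itself (tie-break documented;
cannot occur at the defaults).

## Problem sizes

The test suite and acceptance script run at the scales the analyses
prescribe: n = 6,033 generation times for parameter recovery, 10⁶ draws
for the model mean, 2,000 channels for the correlation calibration,
500 channels × 20 replicates for death-rate recovery, and 301 series × 20
seeds for the correlation-dimension contrast.  The full suite completes in
a few minutes on one CPU.

## Known limitations

* The copula latent is continuous; discrete-state alternatives fitting the
  same marginal and lag profile are not explored.
* Drug-phase parameters are qualitative defaults, config-exposed; no
  dose-response claim is made.
* The window-extraction inspection bias (above) is documented but not
  corrected; estimating the underlying marginal from windowed cycles would
  require length-biased-sampling corrections out of scope here.
* The correlation-dimension estimator inherits the upward bias of a
  maximum over noisy local slopes; it is validated on benchmarks but its
  absolute values should be read qualitatively (growth vs saturation), not
  as precise dimensions.
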