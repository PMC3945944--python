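# Methods

`foragedive` implements a complete analysis chain for predicting foraging
success (prey capture attempts, PCA) of a diving marine predator from its
dive profile alone, validated end-to-end on synthetic data with known
ground truth. This note records the models, the numerical choices, and what
the synthetic validation does and does not demonstrate.

## Signal model and segmentation

Depth is sampled at 1 Hz, positive downward, in metres. Pressure
transducers drift, so the raw record is first re-zeroed: surface records
(the minimum depths between successive dives, plus the leading and trailing
surface segments) anchor a trend — a robust straight line when fewer than
10 anchors exist, otherwise a cubic smoothing spline whose smoothing scale
comes from the local roughness of the anchors (held constant beyond the
first/last anchor; no extrapolation). The trend is subtracted everywhere;
negative residual depths are preserved for inspection.

A *dive* is any excursion beyond 3 m, extended outward to the adjacent
surface crossings (0.5 m). Phases use the 0.4 m/s vertical-rate threshold
on plain 1-s first differences — no smoothing, since the sampling grid
defines the rate resolution. Scanning forward, the descent survives slow
runs that qualify as transit *steps* (shorter than 8 s and at a mean depth
under 60 % of maximum dive depth); the first disqualifying slow run starts
the bottom phase. A slow run of 8 s or more starts the bottom regardless of
depth — the step definition requires "< 8 s", so longer plateaus cannot be
steps, and treating them as bottom onset is the deterministic, conservative
completion of the rule. The ascent is segmented symmetrically scanning
backward; on V-shaped dives the two scans may touch, yielding a zero-length
bottom. Dives not exceeding 15 m are detected and timed but carry no phase
metrics and never enter the models (their short duration makes phase
parameters meaningless, and they reflect a different foraging mode).

Descent rate is depth at bottom start divided by descent duration; ascent
rate is depth at bottom end divided by ascent duration.

## Dive features

All features are run-based on the same first differences, with runs
strictly maximal (a single discordant sample splits a run — no gap
tolerance):

* transit steps (descent/ascent): |rate| < 0.4 m/s for 1–7 s before 60 % of
  maximum depth;
* bottom steps: |rate| > 0.4 m/s for 1–7 s inside the bottom phase,
  descending (deeper) or ascending (shallower) by sign — "descending" is
  read in the depth frame (downward staircase), matching how such pursuit
  steps appear in real profiles;
* wiggles: an ascending bottom step followed, within less than 3 s
  (end-of-first to start-of-second), by a descending bottom step; pairing
  is greedy in time order and each step joins at most one wiggle. The
  symmetric either-order reading exists behind a config switch, off by
  default;
* bottom depth variation: maximum dive depth minus depth at bottom start
  (negative only when the maximum precedes the bottom — flagged, kept).

## Bout structure

Post-dive surface intervals mix a fast within-bout recovery process and a
slow between-bout one. The criterion variable (absolute successive
differences of post-dive intervals by default; raw intervals optional) is
fitted with a two-component exponential mixture by direct likelihood
maximisation (Nelder–Mead from three moment-based starts, best likelihood
wins). The bout-ending criterion (BEC) is the closed-form crossing of the
weighted component densities:

    x* = log((p λ_f) / ((1 − p) λ_s)) / (λ_f − λ_s)

A difference threshold cannot delimit bouts directly, so the BEC is applied
to the raw post-dive intervals: any interval above it ends a bout. Bouts
with fewer than 3 dives are excluded entirely, and the terminal dive of
every bout is excluded (its surface interval reflects behaviours other than
recovery). Degenerate inputs — fewer than 20 intervals, all-identical
values, or a collapsed mixture (fast rate not exceeding slow rate at the
optimum) — raise errors rather than returning a criterion.

## Prey-capture-attempt detection

The horizontal jaw-acceleration channel (16 Hz) is high-passed at 3 Hz
(4th-order Butterworth, forward–backward so zero-phase; attenuation at
1.5 Hz is ≈ −48 dB and pass-band ripple above 4.5 Hz under 0.4 dB), then a
centred 1.5-s moving-window sample variance is computed (24 samples at
16 Hz; truncated windows at the edges). Hall-sensor records run the same
pipeline with a 5-s window and no high-pass — the sensor's slow return to
baseline needs the wider window, and the channel carries no body-motion
component to remove.

"Extreme" variance is defined per individual and robustly: threshold =
median + k·MADn with MADn = 1.4826 × median absolute deviation and k = 6 by
default, so the events themselves cannot drag the threshold. A moment rule
(mean + k·sd) and an absolute threshold are available. Super-threshold runs
separated by less than 0.5 s merge. The moving window flattens each burst
into a ≈ (window + burst)-wide plateau, so run maxima localise poorly; each
event is therefore placed at the threshold-excess-weighted centroid, and —
for the accelerometer path — a 5-sample short-window variance of the same
filtered signal refines the runs: events sit at its super-threshold peaks
(≥ 0.75 s apart), which splits adjacent bursts whose plateaus touch, and a
run in which the short-window series never spikes is rejected as a chance
variance excursion (over multi-day records these otherwise accumulate).
Two bursts closer than the variance window still merge into one event, as
the window cannot resolve them.

Events map to the dive whose span contains them; surface events are counted
and logged but never modelled.

## Aggregation scales

Tables are built at six scales: dive, bout, 30-min / 1-h / 2-h windows
inside bouts, and whole nights. Super-dive rows sum the response, average
the per-dive predictors, and add the number of dives and `pct_time_deep` —
the percentage of the row's span covered by deep-dive cycles (dive duration
plus following surface interval). Bout and window rows survive only if that
coverage exceeds 85 %. Windows are anchored at each bout's first dive and
tile without overlap; partial trailing windows are dropped (the simplest
reproducible choice — anchoring/overlap is otherwise arbitrary — and it
makes the 30-min windows nest exactly inside the 1-h and 2-h ones). Dives
belong to the window containing their start. Night rows require the
recording to cover the whole night window; night boundaries are explicit
configuration (for synthetic data, the generator's truth), not solar
geometry.

Predictors are standardized (centred, unit variance) per fitting table;
during cross-validation the training fold's statistics are reused on the
held-out fold. A zero-variance predictor is an error naming the column.

## Count models, selection, averaging

PCA counts follow a Poisson log-link regression with an individual random
intercept:

    count_ij ~ Poisson(μ_ij),  log μ_ij = x_ij·β + b_i,  b_i ~ N(0, σ_b²)

The marginal likelihood integrates b by adaptive Gauss–Hermite quadrature
(15 nodes by default; the per-individual integrand is exp(S b − E e^b)
with S the summed counts and E the summed exp(linear predictor), so the
posterior mode and curvature come from a scalar Newton iteration and the
grid is centred and scaled there). Optimization is L-BFGS-B on (β, log σ_b)
with an analytic gradient (the adapted grid held fixed — at ≥ 10 nodes the
quadrature is near-exact, so the adaptation terms are negligible; the
gradient matches finite differences to ~1e-8). σ_b is bounded in
[1e-3, 5]; standard errors come from the observed information (central
differences of the analytic gradient), computed lazily for the models that
need them. The fitter agrees with lme4's `glmer(nAGQ=15)` to about four
decimals on coefficients and σ_b. The night scale has too few rows for a
random effect and uses a plain Poisson GLM (Newton iteration, checked
against statsmodels to machine precision).

All predictor subsets up to a per-scale cap are fitted and ranked by AICc,
with k counting intercept, slopes, and (when present) σ_b. Caps default to
11 (dive), 7 (bout), 13 (30-min and 1-h), 4 (2-h) and 2 (night), further
limited so that every tested variable has at least 10 rows. Akaike weights
are computed over the full enumeration; the candidate set is the smallest
weight-ordered prefix whose cumulative weight exceeds 0.95, re-normalised
before averaging. Averaging is full (zero-substitution): a predictor absent
from a candidate contributes a zero coefficient, so rarely-selected
predictors show near-zero averaged effects with importance weights near
zero. Unconditional standard errors combine within-model variance and
between-model spread (Burnham–Anderson). Non-converged fits are dropped
from the ranking with a warning rather than aborting the enumeration.

## Validation

The concordance index (Harrell's C, via lifelines — the same statistic as
Hmisc's `rcorr.cens`) scores, over all pairs with unequal observed counts,
whether the prediction ordering matches (ties in prediction score one
half). Bands: > 0.9 excellent, 0.8–0.9 good, 0.7–0.8 reasonable, 0.6–0.7
poor, 0.5–0.6 unsuccessful, with boundary values in the lower band (so a C
of exactly 0.70 is "poor"); values below 0.5 are flagged anti-concordant.

Cross-validation leaves each individual out in turn ("all possible
combinations of individuals" is read as each animal held out exactly once —
all subset splits would be combinatorially explosive and contradict
"leave-one-out"), reruns selection and averaging on the remainder, and
predicts the held-out animal at population level (random intercept zero).
Two summaries are reported: the pooled C over all held-out rows (headline)
and the mean per-individual C (diagnostic). They answer different
questions. Pooling includes between-animal pairs, and under leave-one-out
those carry a small structural anti-concordant bias: the fold's fixed
intercept is estimated without the held-out animal, so it anti-correlates
with that animal's random intercept; with no signal at all the pooled C
settles below 0.5, while the within-animal fold-mean C sits at 0.5 as a
null statistic should. Null calibration should therefore be judged on the
fold-mean C, discrimination of new animals on the pooled C.

## What the synthetic generator emulates — and what it does not

The generator produces multi-day trips (default 11 individuals × 9 nights,
matching deployment scales for lactating otariid females) of night-active
dive bouts: geometric bout sizes (mean 40 dives), exponential within-bout
surface intervals (mean 40 s) and between-bout gaps (mean 30 min) inside
explicit night windows (21:00–05:00). Dives are piecewise-linear
trapezoids built on the integer-second grid (lognormal entry depths,
median 40 m; transit speeds 0.8–1.4 m/s; lognormal bottom durations,
median 45 s) with injected transit-step plateaus, bottom staircases and
wiggles (amplitudes ≥ 1.1 m, rates 0.55–1.1 m/s, components separated by
≥ 4 s of flat water so truth counts are unambiguous), a configurable linear
surface-offset drift (default 1 m over the trip) and Gaussian depth noise
(default 0.1 m, the sensor resolution). About 10 % of dives stay under
15 m. True PCA counts are drawn from the Poisson log-link model on the
dive's own (within-trip standardized) predictors — default coefficients
follow the magnitudes estimated for Antarctic fur seals at the dive scale,
with a random-intercept sd of 0.3 — and each count injects one 0.3-s,
10×-baseline-sd transient (6-Hz carrier under a Hann window) into the
16-Hz acceleration channel, on top of white noise and a 0.35-Hz body-sway
component.

Because profiles are integer-second piecewise-linear, noise-free
segmentation and feature recovery are *exact*; this validates the
detectors' logic, not their robustness to real-profile curvature. The burst
waveform is a stand-in — nothing quantitative is published about mouth-
opening accelerometry morphology — so detection results validate the
variance-threshold machinery under the stated burst model, not performance
on a particular logger. Swim speed, hydrodynamics, Hall-sensor voltage
physics, prey handling and broken-surface intervals are not modelled.
Passing tests therefore demonstrate correctness of every algorithmic step
and recoverability of known structure at realistic noise levels; they do
not certify field performance on any specific instrument.

## Problem sizes used by the test suite and acceptance script

Chosen so every experiment still has overwhelming statistical resolution:
segmentation recovery on ≥ 200 noisy dives; feature oracles on 100 random
profiles; bout-criterion recovery over 100 replicates of 1000 intervals;
detection performance over 5 single-night seeds; mixed-model recovery over
100 replicates of 2000 dives × 10 individuals (σ_b = 0.5); selection
behaviour over 50 replicates of 1000 dives with 11 candidates capped at 5
(the ±0.3 effects have |z| ≈ 10 there, so the cap and size cost no power);
C-index benchmarks on 1200 rows × 10 individuals, with the strong-signal
benchmark generated at intercept 1.5 and σ_b = 0.3 — conditions fixed in
advance from the ceiling calculation C(y, λ_true) ≈ 0.75; and the
determinism check on a full 5-individual, 2-night pipeline run.

## Known limitations

* The bout-criterion likelihood is one member of the family of
  maximum-likelihood bout methods; the log-frequency and Poisson-process
  variants are not implemented (the criterion variable is switchable).
* Full model averaging shrinks rarely-selected coefficients toward zero by
  construction; conditional averaging is not offered.
* The GLMM supports a single random intercept (individual); random slopes,
  nested grouping, zero inflation and negative-binomial responses are out
  of scope.
* Dive detection assumes the offset correction leaves surface records near
  zero; records with step discontinuities in transducer offset would need
  a piecewise trend.
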