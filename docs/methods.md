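# Methods

This note documents the measurement model, the statistical machinery and
the synthetic-data generator in enough detail to judge what the test suite
does and does not demonstrate.

## Anatomical normalization

Each frame carries pixel coordinates (image convention: columns rightward,
rows downward) for the anterior–inferior corners of C2, C4 and the hyoid.
The anatomical frame is rebuilt per frame: ŷ = (C2 − C4)/‖C2 − C4‖,
x̂ = the orthogonal unit vector pointing anteriorly, and coordinates are
scaled by 100/‖C2 − C4‖ into %(C2–4) units. Two consequences matter:

- **Similarity invariance.** Any rotation + uniform scaling + translation
  of the raw pixels leaves X, Y, XY unchanged (verified to 1e−9 by
  property test). This is the formal sense in which the units remove
  magnification and head-tilt effects.
- **Per-frame scalar.** Because the spine is re-marked on every frame, the
  scalar and axes are recomputed per frame (robust to patient motion); a
  fixed reference frame can be requested instead
  (`track_recording(..., reference_frame=...)`). Whether the original
  rating protocol used per-frame or single-frame normalization is not
  derivable from the outcome tables; per-frame is the default here.

Patient orientation in pixels is not encoded in the data, so the anterior
direction is set by a `facing` flag (default `right`, anterior toward
increasing column). A mean anterior coordinate below zero triggers a
"check facing" warning without altering values, since the hyoid sits
anterior to the spine in any plausible recording.

Absent hyoid landmarks (out of view, shoulder obstruction) propagate as
missing entries end to end — never as zeros, which would alias to "hyoid
at the C4 origin".

## Kinematic outcomes

- **Burst onset.** Rater-annotated burst frames always take precedence;
  they are the reference procedure. The built-in detector is a
  reproducible surrogate: baseline = median XY of the first five present
  frames; onset = first frame exceeding baseline by `delta`
  (default 2 %(C2–4)) followed by `run_length` (default 3) present frames
  of sustained rise within a `delta/4` tolerance. The tolerance rejects
  isolated annotation spikes while allowing small non-monotonicity from
  marking noise.
- **Peak.** Frame of maximal XY at/after the burst, earliest frame on
  exact ties (deterministic; favors shorter time-to-peak). Absent frames
  are skipped.
- **Timing.** time-to-peak = frame count / frame rate; tabulated values
  are rounded to integer ms but speed always uses the unrounded time, so
  no quantization bias enters the ratio. At 30 frames/s all times are
  multiples of 33.3 ms; this granularity is a property of the instrument,
  not a numerical artifact.
- **Speed.** (XY at peak − XY at burst)/elapsed. On noisy tracks the
  difference can be negative (tie-breaking can select a peak frame whose
  measured XY is below the burst value); it is reported as-is rather than
  clamped, and a degenerate peak-at-burst swallow reports 0 with zero
  elapsed time never reaching the division.
- **Failure propagation.** Any stage failure yields a flagged missing
  summary carrying the reason; dataset-level accounting always satisfies
  generated = analyzed + dropped.

## Statistics

- **Descriptives.** Mean, sample SD (n−1), t-based 95% CI, and quartiles
  by linear interpolation between order statistics (the quantile algorithm
  of the original tables is unknown; this choice is documented and
  configurable only in the sense that the raw values are available). The
  CI treats swallows as independent, matching how such reference tables
  are conventionally laid out; a cluster bootstrap over participants is
  available (`descriptive_table(..., ci_method="cluster-bootstrap")`) for
  the clustering-aware alternative.
- **Blom transformation.** Φ⁻¹((rᵢ − 3/8)/(n + 1/4)) with average ranks
  for ties. Applied by default to time-to-peak and speed before modeling
  (right-skewed outcomes); peak position is modeled untransformed.
- **Spearman screening.** Pairwise-complete, average ranks,
  t-approximation p-values. Sip volume is carried into an outcome's mixed
  model iff its screening p < .05 (`force_volume` overrides).
- **Mixed models.** `MixedLM` (REML) with fixed effects
  stimulus (9 levels) + volume + stimulus:volume, a participant random
  intercept, and a participant×stimulus variance component which makes the
  three repetitions of a stimulus within a participant equicorrelated —
  the compound-symmetry repeated-measures structure. Optimization uses
  Powell with an L-BFGS fallback; non-convergence and degenerate designs
  (single participant) are surfaced in the result, never silently.
- **F tests.** Type-III style Wald tests with the covariate centered at
  its sample mean: the stimulus test compares levels at the mean sip
  volume; the volume main effect is the unweighted average of the nine
  within-stimulus slopes (1 df); the interaction is the 8-df
  slope-heterogeneity test. Denominator df = n − rank(X), a large-sample
  approximation — fractional Satterthwaite-type dfs are deliberately out
  of scope, so printed F/df values are not comparable digit-for-digit with
  SPSS output on other data. Null simulations (500 replicates, 20
  participants × 9 stimuli × 3 repetitions) give empirical type-I error
  0.046–0.050 at α = .05 for all three terms.
- **Post hoc.** All 36 pairwise stimulus contrasts as adjusted-mean
  differences at the observed covariate mix, Wald z p-values,
  Šidák-adjusted with family size 36.
- **Power caveat.** The volume main-effect test averages slopes over all
  nine stimuli. Spoon-administered boluses (moderately/extremely thick)
  have volume SD ≈ 1 ml, so their slopes are nearly unidentifiable and
  the averaged test has low power against a weak coupling: at the default
  0.3 %(C2–4)/ml (chosen to reproduce a marginal rank correlation of
  ≈ .15 among cup sips) power is only ~15% even at ~975 swallows. The
  test-suite power property therefore injects 1.5 %(C2–4)/ml, where power
  is ≈ 99%.

## Synthetic cohorts

The generator's purpose is study-shaped data with known ground truth, not
biomechanics. Defaults encode the study conditions: 39 participants × 27
boluses (3 thin cup sips; 3 starch + 3 gum boluses at each of four
thickened IDDSI levels; spoon administration for the two thickest), 30
frames/s, per-stimulus outcome means and SDs set to the healthy-adult
reference values (peak XY ≈ 168–170 ± 14–18 %(C2–4); time-to-peak
≈ 376–410 ± 91–137 ms; speed ≈ 112–128 ± 34–54 %(C2–4)/s), and
whole-recording missingness probability 78/1053 so the expected number of
trackable swallows matches the reported 975.

Per swallow: peak XY ~ Normal(stimulus mean, residual SD) + participant
intercept (SD 11.3 %(C2–4), i.e. intraclass correlation ≈ 0.5 at the
thin-liquid marginal SD of 16 — a placeholder to exercise the mixed
model, as the true repetition correlation is unreported) + volume
coupling; time-to-peak drawn in ms and discretized to whole frames
(reproducing the 33 ms granularity of tabulated quartiles; minimum 2
frames); speed drawn from its stimulus distribution and converted to the
burst-to-peak displacement, so the three outcomes are mutually consistent.
A physical floor keeps the rest position at ≥ 20 %(C2–4); jointly extreme
draws are reconciled by clamping rest and recording the implied effective
speed as truth (≪ 1% of swallows). Sip volumes: cup sips log-normal
(median 18 ml, σ_log 0.4), spoon boluses normal truncated to (0, 10] ml
(mean 5, SD 1) — literature-plausible placeholders, as the study reports
no volume table.

The trajectory is a rest plateau, a smoothstep rise to the peak over the
drawn frame count along a fixed anterosuperior ray (60/40
anterior/superior split), and a smoothstep descent at the same pace; the
emitted window runs from 5 frames before the burst to 5 frames after the
peak, matching rater annotation practice, and the true burst frame is
emitted as the annotation.

**Annotation-error model.** Marking error decomposes into a per-recording
systematic offset (a rater's consistent placement choice on a clip) and
per-frame scatter: hyoid 0.9 px offset + 0.45 px scatter (~1 px marginal),
spine ±1 px offset + ±0.3 px jitter (uniform). The split is load-bearing:
because the peak is the *maximum* of measured XY, frame-independent
scatter biases recovered peaks and speeds upward (the max of noisy values
exceeds the noisy value of the max), while recording-level offsets do
not. With scatter at these levels the pipeline recovers configured means
essentially unbiased (residual bias ≈ +0.3 %(C2–4) on peak XY, ≈ +1.3
%(C2–4)/s on speed, within Monte-Carlo error of the acceptance checks);
per-swallow peak error on a 60 px spine is within 7 %(C2–4) for ≥ 95% of
swallows (1 px ≈ 1.67 %(C2–4)). A noise model dominated by frame-level
scatter would be equally "1 px" yet inflate recovered speeds by ~4%; real
rating error plausibly contains both components, so recovered values
should be read as a best case for annotation quality.

**What is not emulated.** No biphasic or participant-specific trajectory
shapes, no swallow-to-swallow carryover, no per-stimulus missingness
structure (missingness is homogeneous Bernoulli, though the study
attributes it to field-of-view and shoulder obstruction, which plausibly
vary by posture), no rater drift, no image rendering. Passing recovery
tests therefore shows the measurement and statistics chain is correct and
unbiased under this error model — not that it is robust to every failure
mode of real annotations.

**A deliberate confound.** Because administration route follows
consistency (spoon for the two thickest levels) and spoon volumes are
small, sip volume is confounded with stimulus exactly as in the real
protocol: with table-derived speed means, marginal volume–speed screening
detects an association even at zero injected coupling. Decision-rule
tests use level-uniform outcome means to isolate the screening logic;
analyses of default cohorts should interpret volume effects with the same
caution the original design requires. The `administration` column is
exposed and can be added to the models
(`fit_mixed_model(..., include_administration=True)`), but it is collinear
with the stimulus factor by design.

## Problem sizes and determinism

Simulation-based checks are sized to be decisive yet quick: 500-replicate
null calibration on a 540-observation design, 200-cohort missingness
averaging, single full cohorts (1053 recordings) for end-to-end runs. All
randomness flows through explicit `numpy` generator seeds; identical seed
and configuration give byte-identical output files.
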