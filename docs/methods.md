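# Methods

## The Activity Index

The AI summarises movement in an epoch as the noise-adjusted average of the
three per-axis signal variances, square-rooted back to the acceleration
scale:

    AI_abs(t; H) = sqrt( max( (1/3) [ Σₘ σ²ₘ(t; H) − σ̄² ], 0 ) )

where σ²ₘ(t; H) is the variance of axis m over the H-sample window starting
at sample t and σ̄² is the device's systematic noise variance. The relative
scale divides the bracket by σ̄² before the root, expressing movement in
units of the smallest variability the device can distinguish from its own
noise. Three structural properties follow from the definition and are
enforced by tests:

* **Rotational invariance.** Σₘ σ²ₘ is the trace of the within-window
  covariance matrix — the total second moment about the window's mean
  vector — which is preserved by any orthogonal change of device axes.
* **Additivity.** The 1-second AI is the base resolution; a T-second AI is
  *defined* as the sum of its T consecutive 1-second values, so coarser
  epochs are exact aggregations rather than recomputations.
* **Zero at rest.** The subtraction of σ̄² and the truncation at zero make a
  stationary device score exactly 0 in expectation-neutral fashion: any
  window whose summed variance does not exceed the noise floor scores 0.

Two presentational choices deserve emphasis. First, the defining expressions
are sometimes written without the outer square root; we include it because
the AI is stated to carry the unit g, and a variance difference would be in
g². With the root, the two scales obey the exact identity
AI_rel = AI_abs / sqrt(σ̄²) — note the proportionality constant is the noise
*standard deviation*, not the variance, a point on which textual accounts of
the metric are inconsistent. Second, the relative scale is undefined at
σ̄² = 0 and the code raises rather than falling back silently, to prevent
mixing the two unit systems.

### Variance conventions

The windowed variance uses the unbiased denominator n − 1 by default
(`ddof=1`), and the identical convention is used in noise calibration so the
truncation boundary (window variance vs noise floor) is consistent. At
H = 30 samples the two conventions differ by a factor 30/29 ≈ 3.4% on the
variance scale. The population convention (`ddof=0`) is available as a
parameter; it is the convention under which the closed-form oracle is exact:
a full-period sinusoid of amplitude a sampled on an equispaced grid has
population variance exactly a²/2, giving AI_abs = a/√6 at σ̄² = 0, while the
unbiased convention yields a/√6 · sqrt(H/(H−1)).

Each window is shifted by its first sample before the variance is taken.
Variance is shift-invariant, so this changes nothing mathematically, but it
removes the ~1 g gravity offset that would otherwise dominate the working
precision (and it makes a constant window score exactly zero in floating
point, keeping the "zero at rest" property exact rather than approximate).

Windows are non-overlapping, left-aligned at the first sample, labelled by
their start time, half-open [t, t + H); a trailing partial window is
dropped.

## ENMO

ENMO is the per-sample Euclidean norm of the acceleration vector minus 1 g,
truncated at zero, averaged over the epoch: mean of max(0, ‖x(s)‖ − 1). The
truncation is applied per sample *before* averaging, following the placement
of the max inside the per-sample set in the defining formula; the
average-then-truncate variant is available behind a flag for comparison with
other implementations. Epoch aggregation for ENMO is the mean of 1-second
values (an average-type metric; summing would break its interpretation in
g), whereas AI aggregates by summation.

## Noise calibration

σ̄² is estimated as the sum of the three per-axis means of windowed variances
over still periods. Still periods come from:

1. **Idle sleep mode detection.** The GT3X+ freezes its output after 10 s
   without detected movement, repeating the last sampled value verbatim. The
   detector finds runs of exactly identical samples on all three axes lasting
   at least 10 s; since the frozen run itself has zero variance, the
   calibration window is the 10 seconds of genuine still data ending at the
   freeze (clamped to the recording start when the recording is constant
   from its first sample). Exact repetition across all three axes has
   essentially zero false-positive probability under continuous sensor
   noise, which the detection-specificity test confirms.
2. **A variance threshold** (default 10⁻⁵ g² per axis, configurable) for
   devices without idle mode.
3. **Bench recordings** — the whole recording treated as still (device on a
   desk), which makes the profile accelerometer-specific rather than
   participant-specific.

Per-device values σ̄ᵢ² are pooled by arithmetic mean on the variance scale
(default); pooling the standard deviations instead is available as an option
and differs only in the third decimal for near-equal devices. The pooled
object carries min/max and the coefficient of variation of the σ̄ᵢ² so a
wide spread — a mis-calibrated device — is visible before a single study
value is adopted.

## The session simulator

The simulator emulates a hip-worn 30 Hz recording of a nine-activity
laboratory session spanning sedentary to moderate intensity, with aliases
DVD, PUZZ, DISH, LAUN, WALK, MOP, TM15, TM20, TM25. Each sample is gravity
(1 g, fixed direction) + per-axis sinusoidal movement + i.i.d. Gaussian
sensor noise. Sessions are built in a canonical frame (gravity along +z) and
rotated as a whole to the requested orientation, so the orientation
machinery is exactly neutral for rotation-invariant metrics.

Parameters that matter, with defaults and rationale:

* **Per-axis noise sd, 0.01 g** — noise floor σ̄² = 3 × 10⁻⁴ g², the scale a
  consumer MEMS accelerometer's still signal shows; jittered ±10%
  (log-normal) across devices in cohort simulation.
* **Oscillation amplitudes, 0.005–0.18 g peak**, strictly increasing with
  the activity's MET mean. No published per-activity amplitudes exist for
  this protocol; the defaults are the package's own choice and are intended
  to preserve the ordinal intensity structure only, not measured magnitudes.
* **Gravity-parallel axis weight, 0.15 (sedentary) → 1.0 (walking).**
  Low-intensity movement mostly *tilts* the device — acceleration stays
  orthogonal to gravity and the norm stays near 1 g — while ambulation adds
  vertical impact. This weight is the mechanism that reproduces, in
  direction, the empirical finding the evaluation targets: ENMO (norm-based)
  concentrates near zero for sedentary/light bouts while the AI remains
  positive and graded.
* **MET means 1.0–3.9**, covering sedentary (<1.5), light ([1.5, 3)) and
  moderate (≥3) classes with at least two activities each; realized METs are
  Gaussian draws truncated below at 0.9 (clipping, not resampling).
* **Amplitude jitter 0.2** relative sd second-to-second; per-participant
  common amplitude factor log-normal with sd 0.15.
* **Idle tail, 70 s**: 10 s of genuine still samples (the stillness the
  device must observe before freezing) followed by verbatim repetition of
  the last still sample — the idle-sleep artifact the calibration detector
  keys on.
* **Bout length 120 s** in the default protocol — long enough for stable
  per-bout medians while keeping a 50-participant cohort simulation to a few
  seconds; rest periods between bouts are omitted by default (configurable)
  since evaluation uses annotated bout intervals only.

Randomness is handled by one master seed; per-participant child seeds are
spawned with `numpy.random.SeedSequence`, so cohorts are bitwise
reproducible and extensible.

**What the simulator does not model:** biomechanical gait (harmonics,
asymmetry, impact transients), autocorrelated or non-Gaussian sensor noise,
posture transitions within a bout, non-wear in the middle of a session, and
the breath-by-breath VO₂ measurement process behind real MET values. Tests
passing on this generator therefore validate the metric arithmetic,
calibration, geometry and the *direction* of metric orderings in the
gravity-dominated regime — not absolute AUC or R² levels on any real
population.

## Evaluation

AUC is the Mann–Whitney statistic with ties counted ½ (midranks), computed
via `scipy.stats.rankdata`; it equals the trapezoidal area under the
empirical ROC enumerated at all distinct thresholds, and a brute-force
pairwise-counting oracle checks the equality in tests. Activity-pair tasks
pool second-by-second values across participants within each activity (a
per-participant-median variant is provided as an option; which pooling the
original methodology used for its figure is not fully documented, so the
default is a documented choice, not an asserted fact). Intensity tasks score
each (participant, activity) by its median metric value and label it by the
MET-derived class; the three tasks are sedentary-vs-light, light-vs-MVPA and
MVPA-vs-rest. The positive class of a pair task is the activity with the
higher median MET, so informative metrics score AUC ≥ 0.5 regardless of how
the pair is written. MET association is the Pearson correlation (and its
square) between per-activity median metric and median MET, medians rather
than means throughout. No confidence intervals are attached to AUCs by
default.

## Numerical conventions

* "Exact" identity assertions use relative tolerance 10⁻¹² / absolute
  10⁻¹⁵; rotation invariance is asserted at 10⁻⁹ relative, with the noise
  floor chosen below the operating window variances so no window sits at the
  truncation boundary where the square root amplifies last-bit differences.
* Raw and metric CSVs are written with 17 significant digits and read with
  round-trip float parsing, so write/read cycles are bit-exact.
* Degenerate inputs fail loudly: windows of fewer than two samples, empty
  recordings, σ̄² = 0 on the relative scale, empty ROC classes (naming the
  class), zero-variance correlation inputs, and malformed CSV rows (citing
  the file line) all raise descriptive errors.

## Known limitations

* The proprietary activity count (AC) and its low-frequency extension cannot
  be reimplemented from public information and are outside the package's
  scope; comparisons are AI vs ENMO only.
* Idle-sleep detection requires the artifact's exact-repetition signature;
  compressed or re-quantized exports that perturb repeated values would
  defeat it (use the variance-threshold detector or a bench recording then).
* Still-period identification here serves calibration only; it is not a
  non-wear compliance algorithm.
* The per-axis noise decomposition assumes axis-independent noise; the
  axis-specific relative AI variant (normalising each axis by its own noise
  variance) is not implemented.
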