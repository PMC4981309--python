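# actimetrics

Open, reproducible summary metrics for raw tri-axial accelerometry.

Research-grade accelerometers (e.g. the hip-worn ActiGraph GT3X+) record
30 Hz acceleration on three axes, but most epidemiological analyses still run
on the manufacturer's proprietary *activity counts*, which have no public
formula and vary across devices and software versions. This package
implements a transparent alternative — the **Activity Index (AI)** — together
with the open comparator **ENMO**, the device-noise calibration the AI
requires, a simulator of laboratory activity sessions, and the ROC/MET
evaluation methodology used to benchmark such metrics. It is aimed at
physical-activity and ageing researchers who want raw-data summaries they can
reproduce, compare across devices, and relate to energy expenditure.

## The metrics

For participant *i*, let σ²ᵢₘ(t; H) be the variance of the axis-*m*
acceleration signal (in g) in the window of H samples starting at *t*, and
let σ̄ᵢ² = σ²ᵢ₁ + σ²ᵢ₂ + σ²ᵢ₃ be the device's *systematic noise variance*,
estimated from windows in which the device is not moving. Then

    AI_abs(t; H) = sqrt( max( (1/3) [ Σₘ σ²ᵢₘ(t; H) − σ̄ᵢ² ], 0 ) )        (g)
    AI_rel(t; H) = sqrt( max( (1/3) [ Σₘ σ²ᵢₘ(t; H) − σ̄ᵢ² ] / σ̄ᵢ², 0 ) )  (noise units)

A relative AI of 1 is the smallest variability the device can distinguish
from its own noise; the two scales satisfy AI_rel = AI_abs / σ̄ᵢ exactly.
Because the summed axis variance is the second moment about the window mean
vector, the AI is invariant under any device rotation, and a T-second AI is
defined as the sum of its T consecutive 1-second AIs (additivity).

ENMO is the per-sample Euclidean norm minus one: mean over the epoch of
max(0, ‖x‖ − 1), in g. It responds only to deviations of the acceleration
*norm* from 1 g, which is why it barely registers sedentary and light
movements that merely tilt the device — the regime where the AI, which sees
any windowed variance above the noise floor, keeps discriminating.

Noise calibration exploits the GT3X+ *idle sleep mode*: after 10 s without
detected movement the device repeats the last sample verbatim, so an idle
period appears in the raw export as a long constant run preceded by 10 s of
genuine still samples. Those 10 seconds carry the noise floor; per-device
estimates σ̄ᵢ² are pooled to a study-level σ̄² = Σᵢ σ̄ᵢ²/I. MET-based
evaluation uses MET = VO₂ / 3.5 mL·kg⁻¹·min⁻¹ and the intensity classes
sedentary (MET < 1.5), light (1.5 ≤ MET < 3) and MVPA (MET ≥ 3).

## Worked example

Simulate a 10-participant lab study (nine activities from quiet sitting to
treadmill walking), calibrate each device from its idle-sleep tail, and
evaluate AI against ENMO:

```python
import actimetrics as am
from actimetrics.evaluation import rocs_to_frame

base = am.default_opach_protocol(bout_seconds=120.0)
cohort = am.simulate_cohort(10, base, seed=42)

profiles = [
    am.estimate_noise_profile(s.recording, am.detect_idle_sleep_onsets(s.recording))
    for s in cohort
]
study = am.pool_study_noise(profiles)
print(f"pooled sigma_bar_sq = {study.sigma_bar_sq:.3e} g^2 "
      f"(cv {study.cv_sigma_bar_sq:.2f} across {study.n_devices} devices)")

noise = study.as_profile()
metrics = [am.session_metrics(s, noise) for s in cohort]
print(rocs_to_frame(am.intensity_rocs(cohort, metrics)).to_string(index=False))
print(am.met_association(cohort, metrics).to_string(index=False))
```

prints

```
pooled sigma_bar_sq = 3.220e-04 g^2 (cv 0.20 across 10 devices)
              task metric      auc  n_pos  n_neg
sedentary_vs_light AI_REL 0.993808     34     19
sedentary_vs_light   ENMO 0.907121     34     19
     light_vs_mvpa AI_REL 0.964229     37     34
     light_vs_mvpa   ENMO 0.964229     37     34
      mvpa_vs_rest AI_REL 0.977053     37     53
      mvpa_vs_rest   ENMO 0.977053     37     53
metric  pearson_r  r_squared
AI_REL   0.914798   0.836855
  ENMO   0.876464   0.768189
```

The pooled noise floor recovers the generating value (3 × 0.01² = 3 × 10⁻⁴ g²
before device-to-device spread). Each ROC row is one binary intensity task
scored by per-participant-per-activity median metric values: the AI separates
sedentary from light activity markedly better than ENMO (AUC 0.99 vs 0.91),
both detect moderate activity almost perfectly, and the AI is the stronger
linear correlate of METs (R² 0.84 vs 0.77).

The same workflow is available from the shell:

```sh
actimetrics simulate --out-dir cohort --participants 10 --seed 42
actimetrics calibrate cohort/P000/raw.csv --out noise.csv
actimetrics compute cohort/P000/raw.csv --metric ai --scale rel \
    --noise noise.csv --epoch 60 --out ai60.csv
actimetrics evaluate cohort --out-dir results
```

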