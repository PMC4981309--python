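"""Device-noise calibration from still periods of a raw recording.

The AI formulas need the systematic noise variance ``sigma_bar_sq`` — the sum
of the three per-axis signal variances of a *stationary* device.  This module
finds usable still periods, estimates per-device noise profiles from them,
and pools profiles into a single study-level noise variance.

Still periods can come from three sources:

* the GT3X+ "idle sleep mode" signature: when the device detects no movement
  for 10 consecutive seconds it repeats the last sampled value verbatim until
  movement resumes, so an idle run shows up in the raw export as a long
  constant stretch preceded by ~10 s of genuine still (noise-only) samples;
* a user-supplied annotation (e.g. self-reported non-wear);
* a bench recording (device on a desk), passed as one whole-recording still
  interval — in that case the profile is accelerometer-specific rather than
  participant-specific and can be shared by all wearers of that device.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_metrics import (
    DEFAULT_DDOF,
    EpochGrid,
    NoiseProfile,
    TriaxialRecording,
)

__all__ = [
    "StillAnnotation",
    "StudyNoise",
    "detect_idle_sleep_onsets",
    "detect_still_by_variance",
    "estimate_noise_profile",
    "pool_study_noise",
    "read_still_annotation_csv",
    "write_still_annotation_csv",
    "read_noise_profile_csv",
    "write_noise_profile_csv",
]


@dataclass(frozen=True)
class StillAnnotation:
    """Half-open sample-index intervals during which the device is not moving."""

    intervals: tuple[tuple[int, int], ...]
    source: str = "user_supplied"

    def __post_init__(self) -> None:
        ivals = tuple((int(s), int(e)) for s, e in self.intervals)
        prev_end = 0
        for s, e in ivals:
            if s < 0 or e <= s:
                raise ValueError(f"invalid interval ({s}, {e})")
            if s < prev_end:
                raise ValueError("still intervals must be sorted and non-overlapping")
            prev_end = e
        object.__setattr__(self, "intervals", ivals)

    def __len__(self) -> int:
        return len(self.intervals)

    @classmethod
    def whole_recording(cls, rec: TriaxialRecording) -> "StillAnnotation":
        """Treat an entire (bench) recording as one still interval."""
        return cls(((0, rec.n_samples),), source="bench_recording")


@dataclass(frozen=True)
class StudyNoise:
    """Pooled study-level noise variance with per-device dispersion diagnostics.

    ``sigma_bar_sq`` is the arithmetic mean of the per-device values (variance
    scale, the default) or the squared mean of per-device sigma_bar values
    when pooled on the standard-deviation scale.  The dispersion diagnostics
    (min, max, coefficient of variation) support checking whether one pooled
    value is a reasonable summary — a wide spread flags mis-calibrated
    devices.
    """

    sigma_bar_sq: float
    per_device: tuple[NoiseProfile, ...]
    pooling: str = "variance"
    min_sigma_bar_sq: float = field(init=False)
    max_sigma_bar_sq: float = field(init=False)
    cv_sigma_bar_sq: float = field(init=False)

    def __post_init__(self) -> None:
        vals = np.array([p.sigma_bar_sq for p in self.per_device])
        object.__setattr__(self, "min_sigma_bar_sq", float(vals.min()))
        object.__setattr__(self, "max_sigma_bar_sq", float(vals.max()))
        mean = vals.mean()
        cv = float(vals.std(ddof=0) / mean) if mean > 0 else 0.0
        object.__setattr__(self, "cv_sigma_bar_sq", cv)

    @property
    def n_devices(self) -> int:
        return len(self.per_device)

    def as_profile(self, device_id: str = "study_pooled") -> NoiseProfile:
        """The pooled noise as a NoiseProfile usable by the AI formulas."""
        axes = np.mean([p.axis_noise_sq for p in self.per_device], axis=0)
        # rescale axes so their sum equals the pooled value under either pooling
        total = axes.sum()
        if total > 0:
            axes = axes * (self.sigma_bar_sq / total)
        n = sum(p.n_windows for p in self.per_device)
        return NoiseProfile(tuple(axes), n_windows=max(n, 1), device_id=device_id)


def _constant_runs(samples: np.ndarray) -> list[tuple[int, int]]:
    """Maximal half-open runs [s, e) of consecutive identical (x, y, z) rows."""
    n = samples.shape[0]
    if n < 2:
        return []
    same = np.all(samples[1:] == samples[:-1], axis=1)
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(same):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i + 1))
            start = None
    if start is not None:
        runs.append((start, n))
    return runs


def detect_idle_sleep_onsets(
    rec: TriaxialRecording,
    min_run_seconds: float = 10.0,
    calibration_seconds: float = 10.0,
    max_periods: int | None = None,
) -> StillAnnotation:
    """Locate idle-sleep periods and return their calibration windows.

    The idle-sleep signature is an exact repetition of one (x, y, z) sample on
    all three axes for at least ``min_run_seconds``.  Because the device
    freezes only after ~10 s of detected stillness, the 10 seconds *preceding*
    each frozen run are genuine still samples and carry the device's noise;
    the returned annotation contains that ``calibration_seconds`` window for
    each detected run (clamped to the start of the recording when the run
    begins there, e.g. a recording that is constant from its first sample).

    ``max_periods`` optionally caps how many idle periods are used, earliest
    first.  Returns an empty annotation when no qualifying run exists.
    """
    sr = rec.sample_rate
    min_run = int(round(min_run_seconds * sr))
    cal = int(round(calibration_seconds * sr))
    intervals: list[tuple[int, int]] = []
    for s, e in _constant_runs(rec.samples):
        if e - s < min_run:
            continue
        # the run's first sample is the last genuinely sampled value, so the
        # still window ends just after it
        if s + 1 >= cal:
            intervals.append((s + 1 - cal, s + 1))
        elif s > 0:
            intervals.append((0, s + 1))
        else:  # constant from the very first sample: use the run's own head
            intervals.append((0, min(cal, e)))
    if max_periods is not None:
        intervals = intervals[: int(max_periods)]
    return StillAnnotation(tuple(intervals), source="idle_sleep_detected")


def detect_still_by_variance(
    rec: TriaxialRecording,
    threshold_per_axis: float = 1e-5,
    window_seconds: int = 1,
    ddof: int = DEFAULT_DDOF,
) -> StillAnnotation:
    """Variance-threshold still detector for devices without idle sleep mode.

    Flags every window whose variance is at or below ``threshold_per_axis``
    (g^2) on all three axes, then merges adjacent flagged windows.
    """
    from .core_metrics import windowed_axis_variances

    grid = EpochGrid.for_recording(rec, window_seconds)
    if grid.n_epochs < 1:
        return StillAnnotation((), source="user_supplied")
    axis_vars = windowed_axis_variances(rec, grid, ddof=ddof)
    still = np.all(axis_vars <= threshold_per_axis, axis=1)
    H = grid.epoch_length_samples
    intervals: list[tuple[int, int]] = []
    for k, flag in enumerate(still):
        if not flag:
            continue
        start, end = k * H, (k + 1) * H
        if intervals and intervals[-1][1] == start:
            intervals[-1] = (intervals[-1][0], end)
        else:
            intervals.append((start, end))
    return StillAnnotation(tuple(intervals), source="user_supplied")


def estimate_noise_profile(
    rec: TriaxialRecording,
    still: StillAnnotation,
    window_seconds: int = 1,
    device_id: str = "device",
    ddof: int = DEFAULT_DDOF,
) -> NoiseProfile:
    """Per-axis noise variances averaged over still windows of a recording.

    Each still interval is tiled with non-overlapping windows of
    ``window_seconds``; partial windows are dropped.  The per-axis noise
    variance is the mean of the windowed variances over all such windows, and
    ``sigma_bar_sq`` is their sum.
    """
    H = int(window_seconds) * rec.sample_rate
    if H < 2:
        raise ValueError("calibration window must contain at least 2 samples")
    all_vars: list[np.ndarray] = []
    for s, e in still.intervals:
        if e > rec.n_samples:
            raise ValueError(f"still interval ({s}, {e}) exceeds recording length")
        n_win = (e - s) // H
        if n_win < 1:
            continue
        windows = rec.samples[s : s + n_win * H].reshape(n_win, H, 3)
        # same first-sample shift as the metric path, so the two agree exactly
        all_vars.append((windows - windows[:, :1, :]).var(axis=1, ddof=ddof))
    if not all_vars:
        raise ValueError("still annotation contains no full calibration window")
    axis_vars = np.concatenate(all_vars, axis=0)
    return NoiseProfile(
        tuple(axis_vars.mean(axis=0)),
        n_windows=axis_vars.shape[0],
        device_id=device_id,
    )


def pool_study_noise(
    profiles: Sequence[NoiseProfile], pooling: str = "variance"
) -> StudyNoise:
    """Combine per-device noise profiles into one study-level noise variance.

    ``pooling="variance"`` (default) averages the per-device ``sigma_bar_sq``
    values; ``pooling="sd"`` averages the per-device ``sigma_bar`` standard
    deviations and squares the mean.  For near-identical devices the two
    differ only in the third decimal.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("at least one noise profile is required for pooling")
    if pooling == "variance":
        pooled = float(np.mean([p.sigma_bar_sq for p in profiles]))
    elif pooling == "sd":
        pooled = float(np.mean([p.sigma_bar for p in profiles]) ** 2)
    else:
        raise ValueError(f"pooling must be 'variance' or 'sd', got {pooling!r}")
    return StudyNoise(pooled, tuple(profiles), pooling=pooling)


# ---------------------------------------------------------------------------
# CSV interchange


def write_still_annotation_csv(
    still: StillAnnotation, path: str | Path, device_id: str = "device"
) -> None:
    df = pd.DataFrame(
        [(device_id, s, e) for s, e in still.intervals],
        columns=["device_id", "start_sample", "end_sample"],
    )
    df.to_csv(path, index=False)


def read_still_annotation_csv(
    path: str | Path, source: str = "user_supplied"
) -> StillAnnotation:
    df = pd.read_csv(path)
    required = {"start_sample", "end_sample"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation CSV must have columns {sorted(required)}")
    ivals = tuple(
        (int(r.start_sample), int(r.end_sample)) for r in df.itertuples()
    )
    return StillAnnotation(ivals, source=source)


def write_noise_profile_csv(
    profiles: Sequence[NoiseProfile] | NoiseProfile, path: str | Path
) -> None:
    if isinstance(profiles, NoiseProfile):
        profiles = [profiles]
    df = pd.DataFrame(
        [
            {
                "device_id": p.device_id,
                "s1sq": p.axis_noise_sq[0],
                "s2sq": p.axis_noise_sq[1],
                "s3sq": p.axis_noise_sq[2],
                "sigma_bar_sq": p.sigma_bar_sq,
                "n_windows": p.n_windows,
            }
            for p in profiles
        ]
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_noise_profile_csv(path: str | Path) -> list[NoiseProfile]:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"device_id", "s1sq", "s2sq", "s3sq", "n_windows"}
    if not required.issubset(df.columns):
        raise ValueError(f"noise profile CSV must have columns {sorted(required)}")
    return [
        NoiseProfile(
            (float(r.s1sq), float(r.s2sq), float(r.s3sq)),
            n_windows=int(r.n_windows),
            device_id=str(r.device_id),
        )
        for r in df.itertuples()
    ]
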