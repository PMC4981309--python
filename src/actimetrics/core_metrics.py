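"""Windowed-variance activity metrics for raw tri-axial accelerometry.

This module implements the Activity Index (AI) on its absolute and relative
scales, the ENMO comparator (Euclidean Norm Minus One), and epoch
aggregation, all at a 1-second base resolution.

The absolute-scale AI for an epoch of ``H`` samples starting at ``t`` is

    AI_abs(t; H) = sqrt( max( (1/3) * (sum_m var_m(t; H) - sigma_bar_sq), 0 ) )

where ``var_m`` is the windowed variance of axis ``m`` (m = 1, 2, 3) and
``sigma_bar_sq`` is the device's systematic noise variance (the sum of the
three per-axis variances of a stationary device).  The relative scale divides
the variance excess by ``sigma_bar_sq`` before the square root, so a value of
1 corresponds to the smallest variability the device can distinguish from its
own noise.  Both scales truncate at zero: an epoch whose summed variance does
not exceed the noise floor scores exactly 0.

The outer square root keeps AI_abs in units of g (a variance difference would
be in g^2); with it, the two scales satisfy the exact identity

    AI_rel = AI_abs / sqrt(sigma_bar_sq).

ENMO is per-sample ``max(0, ||x|| - 1)`` in g, averaged over the epoch
(truncation applied before averaging by default).

All accelerations are in units of g throughout; no m/s^2 conversion is
performed anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "Metric",
    "TriaxialRecording",
    "EpochGrid",
    "NoiseProfile",
    "MetricSeries",
    "windowed_axis_variances",
    "ai_absolute",
    "ai_relative",
    "ai_per_second",
    "enmo_per_second",
    "aggregate_ai",
    "aggregate_enmo",
]

#: Default start timestamp for recordings without a meaningful wall clock.
DEFAULT_START = datetime(2000, 1, 1)

#: Default variance denominator convention: n - 1 (unbiased sample variance).
#: Must match between metric computation and noise calibration so the
#: zero-truncation boundary is consistent.
DEFAULT_DDOF = 1


class Metric(str, Enum):
    """Names of the supported epoch metrics."""

    AI_ABS = "AI_ABS"
    AI_REL = "AI_REL"
    ENMO = "ENMO"


@dataclass(frozen=True)
class TriaxialRecording:
    """A fixed-rate sequence of tri-axial acceleration samples in g.

    Parameters
    ----------
    samples
        Array of shape ``(n, 3)``; columns are the device axes x, y, z.
    sample_rate
        Samples per second (nominally 30 for the GT3X+ raw export).
    start_time
        Wall-clock time of the first sample.
    """

    samples: np.ndarray
    sample_rate: int
    start_time: datetime = DEFAULT_START

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError(f"samples must have shape (n, 3), got {arr.shape}")
        if arr.shape[0] < 1:
            raise ValueError("recording must contain at least one sample")
        if not np.all(np.isfinite(arr)):
            raise ValueError("acceleration samples must be finite")
        if int(self.sample_rate) <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "sample_rate", int(self.sample_rate))

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_seconds(self) -> float:
        return self.n_samples / self.sample_rate

    def rotated(self, rotation: np.ndarray) -> "TriaxialRecording":
        """Apply a 3x3 proper rotation sample-wise and return a new recording."""
        R = _check_rotation(rotation)
        return TriaxialRecording(self.samples @ R.T, self.sample_rate, self.start_time)


def _check_rotation(rotation: np.ndarray) -> np.ndarray:
    R = np.asarray(rotation, dtype=float)
    if R.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {R.shape}")
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or not np.isclose(
        np.linalg.det(R), 1.0, atol=1e-8
    ):
        raise ValueError("rotation must be orthogonal with determinant +1")
    return R


@dataclass(frozen=True)
class EpochGrid:
    """Contiguous, non-overlapping analysis windows left-aligned at sample 0.

    A trailing partial window (fewer than ``epoch_length_samples`` samples)
    is excluded.
    """

    epoch_length_samples: int
    n_epochs: int

    def __post_init__(self) -> None:
        if self.epoch_length_samples < 1:
            raise ValueError("epoch_length_samples must be positive")
        if self.n_epochs < 0:
            raise ValueError("n_epochs must be non-negative")

    @property
    def epoch_starts(self) -> np.ndarray:
        return np.arange(self.n_epochs) * self.epoch_length_samples

    @classmethod
    def for_recording(
        cls, rec: TriaxialRecording, epoch_seconds: int = 1
    ) -> "EpochGrid":
        """One-second (or multi-second) grid covering the whole recording."""
        if int(epoch_seconds) < 1:
            raise ValueError("epoch_seconds must be a positive integer")
        H = int(epoch_seconds) * rec.sample_rate
        return cls(epoch_length_samples=H, n_epochs=rec.n_samples // H)


@dataclass(frozen=True)
class NoiseProfile:
    """Systematic noise variances of one device/participant.

    ``axis_noise_sq`` holds the per-axis variances (g^2) averaged over still
    windows; ``sigma_bar_sq`` is their sum, the device noise floor used by
    the AI formulas.
    """

    axis_noise_sq: tuple[float, float, float]
    n_windows: int = 1
    device_id: str = "device"
    sigma_bar_sq: float = field(init=False)

    def __post_init__(self) -> None:
        axes = tuple(float(v) for v in self.axis_noise_sq)
        if len(axes) != 3:
            raise ValueError("axis_noise_sq must have three components")
        if any(v < 0 for v in axes):
            raise ValueError("axis noise variances must be non-negative")
        if self.n_windows < 1:
            raise ValueError("n_windows must be at least 1")
        object.__setattr__(self, "axis_noise_sq", axes)
        object.__setattr__(self, "sigma_bar_sq", float(sum(axes)))

    @classmethod
    def noiseless(cls, device_id: str = "ideal") -> "NoiseProfile":
        """A zero-noise profile (sigma_bar_sq = 0); valid only for AI_abs."""
        return cls((0.0, 0.0, 0.0), n_windows=1, device_id=device_id)

    @property
    def sigma_bar(self) -> float:
        """Noise floor on the standard-deviation scale, in g."""
        return float(np.sqrt(self.sigma_bar_sq))


@dataclass(frozen=True)
class MetricSeries:
    """Epoch-indexed values of one metric at a stated epoch length.

    Values are non-negative by definition of every supported metric
    (truncation at zero is part of each formula).  AI_ABS is in g, AI_REL
    and ENMO are reported as dimensionless (ENMO numerically in g).
    """

    metric_name: Metric
    epoch_length_seconds: int
    values: np.ndarray
    start_time: datetime = DEFAULT_START

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not np.all(np.isfinite(vals)):
            raise ValueError("metric values must be finite")
        if vals.size and vals.min() < 0:
            raise ValueError("metric values must be non-negative")
        if int(self.epoch_length_seconds) < 1:
            raise ValueError("epoch_length_seconds must be a positive integer")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "metric_name", Metric(self.metric_name))
        object.__setattr__(
            self, "epoch_length_seconds", int(self.epoch_length_seconds)
        )

    def __len__(self) -> int:
        return self.values.size

    @property
    def epoch_start_times(self) -> list[datetime]:
        step = timedelta(seconds=self.epoch_length_seconds)
        return [self.start_time + i * step for i in range(len(self))]


def windowed_axis_variances(
    rec: TriaxialRecording, grid: EpochGrid, ddof: int = DEFAULT_DDOF
) -> np.ndarray:
    """Per-axis variance of the raw signal in every grid window.

    Returns an array of shape ``(n_epochs, 3)`` in g^2, row ``k`` holding
    the three axis variances of window ``k``.

    ``ddof=1`` (default) is the unbiased sample-variance convention; the same
    convention must be used for noise calibration so the AI truncation
    boundary is consistent.
    """
    H = grid.epoch_length_samples
    if H < 2:
        raise ValueError("window length must be at least 2 samples for a variance")
    if grid.n_epochs < 1:
        raise ValueError("grid contains no full window")
    end = grid.n_epochs * H
    if end > rec.n_samples:
        raise ValueError("grid windows extend beyond the recording")
    windows = rec.samples[:end].reshape(grid.n_epochs, H, 3)
    # shift each window by its first sample: variance is shift-invariant, and
    # removing the ~1 g gravity offset avoids cancellation error (a constant
    # window then has variance exactly 0)
    return (windows - windows[:, :1, :]).var(axis=1, ddof=ddof)


def _sum_vars(axis_vars: np.ndarray) -> np.ndarray:
    v = np.asarray(axis_vars, dtype=float)
    if v.shape[-1] != 3:
        raise ValueError("axis variances must have three components")
    if np.any(v < 0):
        raise ValueError("axis variances must be non-negative")
    return v.sum(axis=-1)


def ai_absolute(axis_vars: np.ndarray, noise: NoiseProfile) -> np.ndarray:
    """Absolute-scale AI, in g, from per-window axis variances.

    Accepts a single variance triple or an ``(n, 3)`` array; returns a scalar
    or an ``(n,)`` array accordingly.
    """
    total = _sum_vars(axis_vars)
    radicand = np.maximum((total - noise.sigma_bar_sq) / 3.0, 0.0)
    return np.sqrt(radicand)


def ai_relative(axis_vars: np.ndarray, noise: NoiseProfile) -> np.ndarray:
    """Relative-scale AI (dimensionless): variance excess in noise-floor units.

    Equals ``ai_absolute / sqrt(sigma_bar_sq)``.  Raises if the noise floor is
    zero, since the relative scale is then undefined — use the absolute scale.
    """
    if noise.sigma_bar_sq <= 0:
        raise ValueError(
            "relative AI is undefined for sigma_bar_sq = 0; use the absolute scale"
        )
    total = _sum_vars(axis_vars)
    radicand = np.maximum(
        (total - noise.sigma_bar_sq) / (3.0 * noise.sigma_bar_sq), 0.0
    )
    return np.sqrt(radicand)


def ai_per_second(
    rec: TriaxialRecording,
    noise: NoiseProfile,
    scale: str = "abs",
    ddof: int = DEFAULT_DDOF,
) -> MetricSeries:
    """Second-by-second AI of a recording on the requested scale.

    ``scale`` is ``"abs"`` or ``"rel"``.  One second is the base resolution;
    coarser epochs are obtained with :func:`aggregate_ai`.
    """
    grid = EpochGrid.for_recording(rec, 1)
    axis_vars = windowed_axis_variances(rec, grid, ddof=ddof)
    if scale == "abs":
        vals, name = ai_absolute(axis_vars, noise), Metric.AI_ABS
    elif scale == "rel":
        vals, name = ai_relative(axis_vars, noise), Metric.AI_REL
    else:
        raise ValueError(f"scale must be 'abs' or 'rel', got {scale!r}")
    return MetricSeries(name, 1, vals, rec.start_time)


def enmo_per_second(
    rec: TriaxialRecording, truncate_before_average: bool = True
) -> MetricSeries:
    """Second-by-second ENMO: mean over the window of max(0, ||x|| - 1).

    By default each sample's (norm - 1) is truncated at zero before
    averaging.  ``truncate_before_average=False`` averages first and truncates
    the window mean instead — provided only for comparison with other
    conventions in the literature.
    """
    grid = EpochGrid.for_recording(rec, 1)
    if grid.n_epochs < 1:
        raise ValueError("recording is shorter than one full second")
    H = grid.epoch_length_samples
    norms = np.linalg.norm(rec.samples[: grid.n_epochs * H], axis=1)
    resid = (norms - 1.0).reshape(grid.n_epochs, H)
    if truncate_before_average:
        vals = np.maximum(resid, 0.0).mean(axis=1)
    else:
        vals = np.maximum(resid.mean(axis=1), 0.0)
    return MetricSeries(Metric.ENMO, 1, vals, rec.start_time)


def _reblock(series: MetricSeries, target_epoch_seconds: int) -> np.ndarray:
    target = int(target_epoch_seconds)
    if target < 1:
        raise ValueError("target epoch must be a positive integer number of seconds")
    if series.epoch_length_seconds != 1:
        raise ValueError("aggregation starts from a 1-second series")
    n_out = len(series) // target
    return series.values[: n_out * target].reshape(n_out, target)


def aggregate_ai(series: MetricSeries, target_epoch_seconds: int) -> MetricSeries:
    """Aggregate a 1-second AI series to a coarser epoch by summation.

    AI is additive across time: the AI of a ``T``-second epoch is the sum of
    its ``T`` consecutive 1-second AIs.  A trailing incomplete block is
    dropped.  ENMO is not additive (it is an average-type metric); use
    :func:`aggregate_enmo`.
    """
    if series.metric_name not in (Metric.AI_ABS, Metric.AI_REL):
        raise ValueError(
            f"additive aggregation is defined only for AI, not {series.metric_name.value}"
        )
    blocks = _reblock(series, target_epoch_seconds)
    return MetricSeries(
        series.metric_name, int(target_epoch_seconds), blocks.sum(axis=1),
        series.start_time,
    )


def aggregate_enmo(series: MetricSeries, target_epoch_seconds: int) -> MetricSeries:
    """Aggregate a 1-second ENMO series to a coarser epoch by averaging.

    The mean preserves ENMO's interpretation in g; summation would not.
    """
    if series.metric_name is not Metric.ENMO:
        raise ValueError("aggregate_enmo applies only to ENMO series")
    blocks = _reblock(series, target_epoch_seconds)
    return MetricSeries(
        Metric.ENMO, int(target_epoch_seconds), blocks.mean(axis=1), series.start_time
    )
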