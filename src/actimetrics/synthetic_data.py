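"""Simulated tri-axial accelerometer recordings of a lab activity session.

The simulator emulates a hip-worn 30 Hz tri-axial accelerometer during a
laboratory protocol of nine everyday activities ranging from quiet sitting to
moderate-intensity walking, paired with per-activity energy expenditure in
METs.  Each sample is

    gravity (1 g, constant direction) + oscillatory movement + sensor noise,

with the movement modelled as per-axis sinusoids whose amplitude is jittered
second-to-second.  This is deliberately not a biomechanical gait model: every
property the metrics depend on — second-moment structure within windows,
deviation of the vector norm from 1 g, rotational geometry — is captured by
a sinusoid-plus-noise signal.

Two device characteristics matter for the metrics and are reproduced:

* **Orientation**: the session is built in a canonical frame with gravity
  along +z and low-intensity movement mostly orthogonal to gravity (tilting
  and fidgeting change the device's orientation but barely its acceleration
  norm), while ambulatory bouts add a substantial gravity-parallel (impact)
  component.  The whole recording is then rotated so gravity points along the
  requested orientation, plus an optional extra device rotation.  This is the
  mechanism behind ENMO's insensitivity to sedentary/light activity: norms
  stay near 1 g, so the per-sample (norm - 1) truncates to ~0, whereas the
  windowed variance behind the AI still sees the movement.
* **Idle sleep mode**: at the end of the session an idle tail is appended —
  up to 10 s of genuine still samples (gravity + noise, the stillness the
  device must observe before it freezes) followed by verbatim repetition of
  the last still sample.  This gives the noise-calibration module the same
  raw-data signature a GT3X+ export shows.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_metrics import TriaxialRecording, _check_rotation

__all__ = [
    "ActivityBoutSpec",
    "SessionSpec",
    "LabSession",
    "simulate_session",
    "simulate_cohort",
    "default_opach_protocol",
    "session_spec_to_dict",
    "session_spec_from_dict",
]

#: Seconds of genuine still data recorded before the device freezes.
IDLE_SETTLE_SECONDS = 10


@dataclass(frozen=True)
class ActivityBoutSpec:
    """One activity bout: movement parameters plus target energy expenditure.

    ``oscillation_amplitude`` is the per-axis peak amplitude (g) of the
    movement component; ``axis_weights`` scales it per canonical axis
    (x, y orthogonal to gravity; z parallel), so a small third weight keeps
    the acceleration norm near 1 g as in real sedentary movement.
    ``amplitude_jitter`` is the relative second-to-second standard deviation
    of the amplitude.  ``met_mean``/``met_sd`` parameterise the realized MET
    draw (truncated below at 0.9, just under the resting value of 1).
    """

    alias: str
    duration_seconds: float
    oscillation_amplitude: float
    oscillation_freq_hz: float
    met_mean: float
    met_sd: float = 0.2
    amplitude_jitter: float = 0.2
    axis_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.duration_seconds <= 0:
            raise ValueError("duration_seconds must be positive")
        if self.oscillation_amplitude < 0 or self.oscillation_freq_hz < 0:
            raise ValueError("amplitude and frequency must be non-negative")
        if self.met_mean < 0.9:
            raise ValueError("met_mean must be at least 0.9")
        if any(w < 0 for w in self.axis_weights):
            raise ValueError("axis weights must be non-negative")


@dataclass(frozen=True)
class SessionSpec:
    """Full specification of one simulated lab session."""

    bouts: tuple[ActivityBoutSpec, ...]
    sample_rate: int = 30
    noise_sd_per_axis: float = 0.01
    gravity_orientation: tuple[float, float, float] = (0.0, 0.0, 1.0)
    rotation: np.ndarray | None = None
    rest_seconds: float = 0.0
    idle_tail_seconds: float = 70.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "bouts", tuple(self.bouts))
        g = np.asarray(self.gravity_orientation, dtype=float)
        if g.shape != (3,) or not np.isclose(np.linalg.norm(g), 1.0, atol=1e-8):
            raise ValueError("gravity_orientation must be a unit 3-vector")
        object.__setattr__(self, "gravity_orientation", tuple(float(v) for v in g))
        if self.rotation is not None:
            object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        if self.noise_sd_per_axis < 0 or self.rest_seconds < 0:
            raise ValueError("noise_sd_per_axis and rest_seconds must be >= 0")
        if self.sample_rate < 1:
            raise ValueError("sample_rate must be positive")


@dataclass(frozen=True)
class LabSession:
    """Simulated recording with per-activity intervals and realized METs."""

    recording: TriaxialRecording
    bout_intervals: tuple[tuple[str, int, int], ...]
    met_values: dict[str, float]
    truth: SessionSpec | None = None
    participant_id: str = "P000"

    def interval(self, alias: str) -> tuple[int, int]:
        for a, s, e in self.bout_intervals:
            if a == alias:
                return s, e
        raise KeyError(f"no bout with alias {alias!r}")

    @property
    def aliases(self) -> list[str]:
        return [a for a, _, _ in self.bout_intervals]


def _rotation_from_z_to(direction: np.ndarray) -> np.ndarray:
    """Proper rotation taking the canonical +z axis onto ``direction``."""
    z = np.array([0.0, 0.0, 1.0])
    d = np.asarray(direction, dtype=float)
    c = float(np.dot(z, d))
    if np.isclose(c, 1.0, atol=1e-12):
        return np.eye(3)
    if np.isclose(c, -1.0, atol=1e-12):
        # 180 degrees about x
        return np.diag([1.0, -1.0, -1.0])
    v = np.cross(z, d)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _bout_movement(
    bout: ActivityBoutSpec, sample_rate: int, rng: np.random.Generator
) -> np.ndarray:
    """Canonical-frame movement signal for one bout, shape (n, 3)."""
    n_sec = int(round(bout.duration_seconds))
    n = n_sec * sample_rate
    t = np.arange(n) / sample_rate
    phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
    if bout.amplitude_jitter > 0 and n_sec > 0:
        per_sec = np.maximum(
            1.0 + bout.amplitude_jitter * rng.standard_normal(n_sec), 0.0
        )
        amp_t = np.repeat(per_sec, sample_rate)
    else:
        amp_t = np.ones(n)
    movement = np.empty((n, 3))
    for m in range(3):
        movement[:, m] = (
            bout.oscillation_amplitude
            * bout.axis_weights[m]
            * amp_t
            * np.sin(2.0 * np.pi * bout.oscillation_freq_hz * t + phases[m])
        )
    return movement


def simulate_session(spec: SessionSpec, participant_id: str = "P000") -> LabSession:
    """Generate one lab session from a spec; bitwise reproducible from its seed."""
    rng = np.random.default_rng(spec.seed)
    sr = spec.sample_rate
    gravity = np.array([0.0, 0.0, 1.0])
    chunks: list[np.ndarray] = []
    intervals: list[tuple[str, int, int]] = []
    met_values: dict[str, float] = {}
    pos = 0
    rest_n = int(round(spec.rest_seconds)) * sr
    for k, bout in enumerate(spec.bouts):
        if k > 0 and rest_n:
            chunks.append(np.tile(gravity, (rest_n, 1)))
            pos += rest_n
        movement = _bout_movement(bout, sr, rng)
        chunks.append(gravity + movement)
        intervals.append((bout.alias, pos, pos + movement.shape[0]))
        pos += movement.shape[0]
        met_values[bout.alias] = max(0.9, float(rng.normal(bout.met_mean, bout.met_sd)))
    # idle-sleep tail: still (noisy) settle period, then frozen repetition
    tail_n = int(round(spec.idle_tail_seconds)) * sr
    settle_n = min(IDLE_SETTLE_SECONDS * sr, tail_n)
    if settle_n:
        chunks.append(np.tile(gravity, (settle_n, 1)))
    samples = np.concatenate(chunks, axis=0)
    if spec.noise_sd_per_axis > 0:
        samples = samples + rng.normal(0.0, spec.noise_sd_per_axis, samples.shape)
    frozen_n = tail_n - settle_n
    if frozen_n > 0:
        samples = np.concatenate(
            [samples, np.tile(samples[-1], (frozen_n, 1))], axis=0
        )
    R = _rotation_from_z_to(np.asarray(spec.gravity_orientation))
    if spec.rotation is not None:
        R = np.asarray(spec.rotation) @ R
    if not np.allclose(R, np.eye(3)):
        samples = samples @ R.T
    rec = TriaxialRecording(samples, sr)
    return LabSession(rec, tuple(intervals), met_values, spec, participant_id)


def default_opach_protocol(
    bout_seconds: float = 120.0, seed: int = 0
) -> SessionSpec:
    """Nine-activity lab protocol in task order, sedentary through moderate.

    Aliases: DVD (watching DVD while sitting), PUZZ (puzzle while sitting),
    DISH (washing dishes), LAUN (laundry), WALK (400 m walk), MOP (dust
    mopping), TM15/TM20/TM25 (treadmill at 1.5/2.0/2.5 mph).  MET means span
    the sedentary (<1.5), light ([1.5, 3)) and moderate (>= 3) classes, with
    oscillation amplitudes strictly increasing in MET rank.  The amplitude
    and frequency defaults are the package's own choices: they preserve the
    ordinal structure of the activity ladder, not any measured magnitudes.
    The gravity-parallel axis weight grows with intensity — sedentary
    fidgeting mostly tilts the device while walking adds vertical impacts.
    """
    d = float(bout_seconds)
    bouts = (
        ActivityBoutSpec("DVD", d, 0.005, 0.6, met_mean=1.0, met_sd=0.10,
                         axis_weights=(1.0, 1.0, 0.15)),
        ActivityBoutSpec("PUZZ", d, 0.013, 0.9, met_mean=1.3, met_sd=0.15,
                         axis_weights=(1.0, 1.0, 0.20)),
        ActivityBoutSpec("DISH", d, 0.022, 1.0, met_mean=1.8, met_sd=0.20,
                         axis_weights=(1.0, 1.0, 0.30)),
        ActivityBoutSpec("LAUN", d, 0.034, 1.1, met_mean=2.1, met_sd=0.20,
                         axis_weights=(1.0, 1.0, 0.40)),
        ActivityBoutSpec("WALK", d, 0.170, 1.9, met_mean=3.8, met_sd=0.30,
                         axis_weights=(1.0, 1.0, 1.0)),
        ActivityBoutSpec("MOP", d, 0.060, 1.3, met_mean=2.8, met_sd=0.25,
                         axis_weights=(1.0, 1.0, 0.60)),
        ActivityBoutSpec("TM15", d, 0.110, 1.7, met_mean=3.1, met_sd=0.25,
                         axis_weights=(1.0, 1.0, 0.90)),
        ActivityBoutSpec("TM20", d, 0.140, 1.85, met_mean=3.4, met_sd=0.25,
                         axis_weights=(1.0, 1.0, 1.0)),
        ActivityBoutSpec("TM25", d, 0.180, 2.0, met_mean=3.9, met_sd=0.25,
                         axis_weights=(1.0, 1.0, 1.0)),
    )
    return SessionSpec(bouts=bouts, seed=seed)


def _random_unit_tilt(
    rng: np.random.Generator, max_tilt_deg: float = 20.0
) -> tuple[float, float, float]:
    """Unit vector within ``max_tilt_deg`` of +z (hip placement wobble)."""
    tilt = np.deg2rad(rng.uniform(0.0, max_tilt_deg))
    azim = rng.uniform(0.0, 2.0 * np.pi)
    v = np.array(
        [np.sin(tilt) * np.cos(azim), np.sin(tilt) * np.sin(azim), np.cos(tilt)]
    )
    return tuple(float(x) for x in v / np.linalg.norm(v))


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix, det fixed)."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def simulate_cohort(
    n_participants: int, base: SessionSpec, seed: int = 0
) -> list[LabSession]:
    """Simulate a cohort of participants as random variations of a base spec.

    Per participant, all bout amplitudes are scaled by a common log-normal
    factor (between-person movement vigour), the noise sd by a smaller
    log-normal factor (device-to-device spread), the gravity orientation is
    tilted randomly within 20 degrees of vertical, and an independent random
    device rotation is applied.  Child seeds are spawned deterministically
    from the master seed, so cohorts are reproducible and extensible.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be at least 1")
    master = np.random.SeedSequence(seed)
    sessions: list[LabSession] = []
    for i, child in enumerate(master.spawn(n_participants)):
        rng = np.random.default_rng(child)
        amp_factor = float(np.exp(rng.normal(0.0, 0.15)))
        noise_factor = float(np.exp(rng.normal(0.0, 0.10)))
        bouts = tuple(
            dataclasses.replace(
                b, oscillation_amplitude=b.oscillation_amplitude * amp_factor
            )
            for b in base.bouts
        )
        spec = dataclasses.replace(
            base,
            bouts=bouts,
            noise_sd_per_axis=base.noise_sd_per_axis * noise_factor,
            gravity_orientation=_random_unit_tilt(rng),
            rotation=_random_rotation(rng),
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        sessions.append(simulate_session(spec, participant_id=f"P{i:03d}"))
    return sessions


# ---------------------------------------------------------------------------
# Spec (de)serialisation for YAML/JSON configs


def session_spec_to_dict(spec: SessionSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["bouts"] = [dataclasses.asdict(b) for b in spec.bouts]
    for b in d["bouts"]:
        b["axis_weights"] = list(b["axis_weights"])
    d["gravity_orientation"] = list(spec.gravity_orientation)
    d["rotation"] = None if spec.rotation is None else np.asarray(spec.rotation).tolist()
    return d


def session_spec_from_dict(d: dict) -> SessionSpec:
    bouts = tuple(
        ActivityBoutSpec(
            **{**b, "axis_weights": tuple(b.get("axis_weights", (1.0, 1.0, 1.0)))}
        )
        for b in d["bouts"]
    )
    rotation = d.get("rotation")
    return SessionSpec(
        bouts=bouts,
        sample_rate=int(d.get("sample_rate", 30)),
        noise_sd_per_axis=float(d.get("noise_sd_per_axis", 0.01)),
        gravity_orientation=tuple(d.get("gravity_orientation", (0.0, 0.0, 1.0))),
        rotation=None if rotation is None else np.asarray(rotation, dtype=float),
        rest_seconds=float(d.get("rest_seconds", 0.0)),
        idle_tail_seconds=float(d.get("idle_tail_seconds", 70.0)),
        seed=int(d.get("seed", 0)),
    )
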