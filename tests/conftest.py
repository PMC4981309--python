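import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import actimetrics as am

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

#: Fixed master seed of the default evaluation cohort (the package's stated
#: study conditions: 50 participants, the 9-activity protocol, 120 s bouts).
COHORT_SEED = 2026
COHORT_N = 50


def make_sinusoid_recording(
    amplitude: float = 0.1,
    freq_hz: float = 2.0,
    seconds: int = 10,
    sample_rate: int = 30,
    axis: int = 0,
    phase: float = 0.0,
) -> am.TriaxialRecording:
    """Noiseless single-axis sinusoid riding on a 1 g z-gravity baseline."""
    t = np.arange(seconds * sample_rate) / sample_rate
    samples = np.tile([0.0, 0.0, 1.0], (t.size, 1))
    samples[:, axis] += amplitude * np.sin(2 * np.pi * freq_hz * t + phase)
    return am.TriaxialRecording(samples, sample_rate)


def make_still_recording(
    noise_sd: float, seconds: int = 100, sample_rate: int = 30, seed: int = 0
) -> am.TriaxialRecording:
    rng = np.random.default_rng(seed)
    n = seconds * sample_rate
    samples = np.tile([0.0, 0.0, 1.0], (n, 1)) + rng.normal(0, noise_sd, (n, 3))
    return am.TriaxialRecording(samples, sample_rate)


def random_rotations(n: int, seed: int = 0) -> list[np.ndarray]:
    """Deterministic list of uniform proper rotations."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        A = rng.standard_normal((3, 3))
        Q, R = np.linalg.qr(A)
        Q = Q @ np.diag(np.sign(np.diag(R)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] = -Q[:, 0]
        out.append(Q)
    return out


@pytest.fixture(scope="session")
def default_cohort() -> list[am.LabSession]:
    """The default seeded evaluation cohort (50 participants, 9 bouts)."""
    base = am.default_opach_protocol(bout_seconds=120.0)
    return am.simulate_cohort(COHORT_N, base, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cohort_noise(default_cohort) -> am.NoiseProfile:
    """Study-pooled noise profile calibrated from each session's idle tail."""
    profiles = [
        am.estimate_noise_profile(
            s.recording,
            am.detect_idle_sleep_onsets(s.recording),
            device_id=s.participant_id,
        )
        for s in default_cohort
    ]
    return am.pool_study_noise(profiles).as_profile()


@pytest.fixture(scope="session")
def cohort_metrics(default_cohort, cohort_noise):
    """Second-by-second AI (relative) and ENMO for every cohort session."""
    return [am.session_metrics(s, cohort_noise) for s in default_cohort]
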