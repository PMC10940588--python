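"""Shared fixtures: small synthetic patients and helper recordings.

Everything is generated programmatically at collection time; the tiny
cohort configuration keeps unit tests fast (short seizures, few channels)
while exercising the same code paths as full-size runs.
"""

import numpy as np
import pytest

from sozmark.io_formats import Recording
from sozmark.synthetic_cohort import CohortConfig, simulate_patient


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_cfg():
    return CohortConfig(
        n_patients=8,
        n_channels=8,
        n_soz=3,
        pre_onset_s=32.0,
        seizure_s=8.0,
        label_noise=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_patient(tiny_cfg):
    """One synthetic patient with a clear SOZ effect (seed fixed)."""
    return simulate_patient(tiny_cfg, 7, patient_id="tiny")


@pytest.fixture(scope="session")
def tiny_recording(tiny_patient):
    return tiny_patient[0]


def make_tone_recording(freqs_per_channel, rate=512.0, duration_s=2.5, amplitude=1.0):
    """Multichannel recording of pure sinusoids, one frequency per channel."""
    t = np.arange(int(round(duration_s * rate))) / rate
    sig = np.vstack([amplitude * np.sin(2 * np.pi * f * t) for f in freqs_per_channel])
    return Recording(
        signal=sig,
        rate=rate,
        channel_labels=[f"c{i}" for i in range(len(freqs_per_channel))],
    )


@pytest.fixture
def tone_recording():
    return make_tone_recording


def random_stable_matrix(n, rho, rng):
    A = rng.standard_normal((n, n)) / np.sqrt(n)
    return A * (rho / np.max(np.abs(np.linalg.eigvals(A))))


@pytest.fixture
def stable_matrix_factory():
    return random_stable_matrix
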