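import numpy as np
import pytest

import fetalqeeg as fq
from fetalqeeg.simulate import scaled_sim_config, short_protocol, tiny_protocol

FS = 256.0


@pytest.fixture(scope="session")
def tiny_subject():
    """One simulated fetus on the minimal (240-s phase) protocol."""
    return fq.simulate_subject(scaled_sim_config(seed=11), tiny_protocol())


@pytest.fixture(scope="session")
def tiny_subject_features(tiny_subject):
    return fq.compute_features(tiny_subject.eeg)


@pytest.fixture(scope="session")
def short_cohort():
    """Nine fetuses on the 720-s-phase protocol with default severity ladder."""
    subjects = fq.simulate_cohort(
        9, scaled_sim_config(), seed=5, protocol=short_protocol()
    )
    qeeg = [fq.compute_features(s.eeg) for s in subjects]
    return subjects, qeeg


def sine(freq_hz, duration_s, amplitude=1.0, fs=FS, phase=0.0):
    t = np.arange(round(duration_s * fs)) / fs
    return amplitude * np.sin(2 * np.pi * freq_hz * t + phase)
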