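import numpy as np
import pytest

import mitransfer as mt


@pytest.fixture(scope="session")
def profile():
    return mt.make_subject(1, 42)


@pytest.fixture(scope="session")
def strong_profile():
    """A subject with a pronounced, fully lateralized ERD."""
    return mt.make_subject(1, 7, overrides=dict(erd_depth=0.6, lateralization=1.0))


@pytest.fixture(scope="session")
def trials(profile):
    return mt.simulate_trials(profile, 20)


@pytest.fixture(scope="session")
def epoched(trials):
    return [mt.preprocess_trial(t) for t in trials]


@pytest.fixture(scope="session")
def images(epoched):
    return [mt.compute_spectrogram(t) for t in epoched]


@pytest.fixture(scope="session")
def small_dataset():
    """3 subjects x 24 trials, spectrograms precomputed; enough to exercise
    every strategy without heavy training."""
    from mitransfer.experiments import spectrogram_dataset

    cohort = mt.simulate_cohort(n_subjects=3, n_trials=24, seed=5)
    return spectrogram_dataset(cohort)


def tone_trial(freq: float, fs: float = 250.0, duration: float = 8.0,
               amplitude: float = 1.0) -> mt.EEGTrial:
    t = np.arange(int(duration * fs)) / fs
    sig = amplitude * np.sin(2 * np.pi * freq * t)
    return mt.EEGTrial(
        subject_id=0, session_id=1, trial_id=0, label="left", fs=fs,
        channels=mt.CHANNELS, signal=np.tile(sig, (3, 1)),
    )
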