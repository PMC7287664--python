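import numpy as np
import pytest
from hypothesis import settings

import accelgait as ag

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def population():
    """Three noiseless profiles drawn from the default event targets."""
    cfg = ag.SynthConfig(n_participants=3, population_seed=7, noise_sd=0.0)
    return ag.generate_population(cfg)


@pytest.fixture(scope="session")
def noiseless_trial(population):
    """10 s at 10 km/h, no accelerometer noise."""
    return ag.simulate_trial(population[0], 10.0, duration=10.0,
                             sample_rate=100.0)


@pytest.fixture(scope="session")
def noisy_trial(population):
    import dataclasses

    profile = dataclasses.replace(population[1], noise_sd=0.8)
    return ag.simulate_trial(profile, 10.0, duration=10.0, sample_rate=100.0)


@pytest.fixture(scope="session")
def filtered_trial(noisy_trial):
    return ag.filter_trial(noisy_trial, ag.FilterSpec())


@pytest.fixture(scope="session")
def windows(filtered_trial):
    return ag.make_windows(filtered_trial)


def make_dummy_trial(participant_id: str, trial_id: str, n: int = 80,
                     seed: int = 0) -> ag.TrialRecord:
    """A minimal well-formed trial for split/windowing bookkeeping tests."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) / 100.0
    return ag.TrialRecord(
        participant_id=participant_id, speed=10.0, sample_rate=100.0, t=t,
        accel=rng.normal(size=(n, 3)), angles=rng.normal(size=(n, 3)),
        heel_height=50 + 10 * np.sin(2 * np.pi * t), trial_id=trial_id)
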