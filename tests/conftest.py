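import numpy as np
import pytest

import sistdetect as sd


@pytest.fixture(scope="session")
def subject():
    return sd.default_subject(0)


@pytest.fixture(scope="session")
def sist_trial(subject):
    """One sit-stand-sit trial (exactly one SiSt and one StSi)."""
    return sd.simulate_trial(subject, activity_id=2, position_id=2, seed=7)


@pytest.fixture(scope="session")
def walking_trial(subject):
    return sd.simulate_trial(subject, activity_id=5, seed=1)


@pytest.fixture(scope="session")
def small_dataset_features():
    """Two-subject reduced protocol with sitting, SiSt and walking trials."""
    return sd.build_dataset_features(2, seed=11, activities=[1, 2, 5, 8],
                                     positions=[0, 2])


@pytest.fixture(scope="session")
def full_dataset():
    """The complete 10-subject protocol: feature bundles + truth metadata.

    Simulated and featurized once per session; raw signals are released as
    soon as each trial is reduced to features.
    """
    trials = sd.simulate_dataset(10, seed=2026)
    durations = []
    counts: dict[int, int] = {}
    seconds = 0.0
    features = []
    while trials:
        t = trials.pop(0)
        durations.extend((b - a) / t.sample_rate
                         for a, b, kind in t.truth_transitions if kind == "SiSt")
        counts[t.subject_id] = counts.get(t.subject_id, 0) + 1
        seconds += t.n_samples / t.sample_rate
        features.append(sd.build_trial_features(t))
    return {
        "features": features,
        "sist_durations": np.array(durations),
        "trials_per_subject": counts,
        "total_seconds": seconds,
    }
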