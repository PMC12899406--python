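import numpy as np
import pytest

from amwfnet.cwt import CwtSpec, build_dataset
from amwfnet.preprocess import preprocess_trial
from amwfnet.synthetic import CohortSpec, simulate_cohort, simulate_trial


@pytest.fixture(scope="session")
def reduced_cwt_spec():
    """Desk-scale scalogram settings used by training-based tests."""
    return CwtSpec(n_scales=32, out_size=(16, 16))


@pytest.fixture(scope="session")
def small_cohort():
    """Four-subject cohort with short trials for generic pipeline tests."""
    spec = CohortSpec(n_subjects_per_group=2, trials_per_action=1,
                      trial_duration=1.5, class_effect_size=1.5, seed=5)
    trials, manifest = simulate_cohort(spec)
    return spec, trials, manifest


@pytest.fixture(scope="session")
def one_trial():
    spec = CohortSpec(seed=5, trial_duration=1.5)
    return simulate_trial(spec, "S01", 3, 1, trial_index=0, stage="active")


@pytest.fixture(scope="session")
def preprocessed_trial(one_trial):
    return preprocess_trial(one_trial)


@pytest.fixture(scope="session")
def small_dataset(small_cohort, reduced_cwt_spec):
    _, trials, _ = small_cohort
    active = [t for t in trials if t.stage == "active"]
    return build_dataset(active, reduced_cwt_spec)
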