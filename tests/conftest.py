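import numpy as np
import pytest

from erpaware import SelectionConfig, generate_dataset, select_trials


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_dataset():
    """3 subjects x 160 trials: cheap, used by unit tests."""
    trials, truth, _ = generate_dataset(n_subjects=3, n_trials=160, seed=42)
    return trials, truth


@pytest.fixture(scope="session")
def study_dataset():
    """24 subjects x 300 trials: the parameter-recovery dataset."""
    trials, truth, _ = generate_dataset(n_subjects=24, n_trials=300, seed=7)
    return trials, truth


@pytest.fixture(scope="session")
def study_analysis(study_dataset):
    trials, truth = study_dataset
    analysis, report = select_trials(trials, SelectionConfig.preset(16, "liberal"))
    return analysis, report, truth
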