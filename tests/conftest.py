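import numpy as np
import pytest

from statenet import build_pattern_set, make_ground_truth, simulate_subject_epochs


@pytest.fixture(scope="session")
def pattern_set():
    return build_pattern_set(seed=1)


@pytest.fixture(scope="session")
def small_epochs():
    """Four-condition epoch set, small enough for fast estimator tests."""
    gt = make_ground_truth(5, 3, 1, 0.0, seed=11)
    return simulate_subject_epochs(gt, n_trials_per_condition=5, n_samples=256, fs=1200.0, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
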