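import numpy as np
import pytest

from sdqprofiles import FitConfig, em_fit, generate, preset
from sdqprofiles.records import ModelSpec, to_score_array


@pytest.fixture(scope="session")
def small_spec():
    return ModelSpec(scales=("a", "b"), informants=("self", "parent"), n_categories=3)


@pytest.fixture(scope="session")
def recovery_dataset():
    """Well-separated three-class dataset at the recovery sample size."""
    config = preset("well_separated", n_subjects=2000, seed=11)
    return generate(config)


@pytest.fixture(scope="session")
def recovery_fit(recovery_dataset):
    """Multi-start EM fit on the recovery dataset (20 starts, fixed seed)."""
    config = recovery_dataset.config
    X = to_score_array(recovery_dataset.subjects, config.spec)
    return em_fit(X, 3, config.spec, FitConfig(n_starts=20, start_iters=30, seed=7))


@pytest.fixture(scope="session")
def moderate_dataset():
    """Moderately separated dataset (entropy R^2 ~ 0.7 regime)."""
    config = preset("moderate", n_subjects=1500, seed=21)
    return generate(config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
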