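import warnings

import numpy as np
import pytest

import fermsense as fs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def shifted_scenario():
    """Source at reference conditions, target at +3 degC with tweaked kinetics."""
    return fs.make_transfer_scenario(
        fs.source_conditions(), fs.target_conditions(), seed=0
    )


@pytest.fixture(scope="session")
def noshift_scenario():
    """Identical source/target conditions: only batch-to-batch variability."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fs.make_transfer_scenario(
            fs.source_conditions(), fs.source_conditions(), seed=0
        )


@pytest.fixture(scope="session")
def quick_config():
    """Reduced tuning budget used throughout the suite (swarm 12, 12 iterations)."""
    return fs.PipelineConfig(swarm_size=12, tune_iters=12)


@pytest.fixture
def small_dataset(rng):
    X = rng.normal(size=(25, 3))
    y = np.sin(X[:, 0]) + 0.5 * X[:, 1] + 0.05 * rng.normal(size=25)
    return fs.Dataset(X, y)
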