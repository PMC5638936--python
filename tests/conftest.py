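import numpy as np
import pytest

from spaft.data_model import SurvivalDataset, standardize
from spaft.pipeline import PipelineConfig
from spaft.simulate import SimulationConfig, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_dataset():
    """5 samples, 3 genes, one censored observation; hand-checkable."""
    X = np.array(
        [
            [0.5, -1.0, 0.2],
            [1.5, 0.3, -0.7],
            [-0.2, 0.8, 1.1],
            [0.9, -0.4, 0.0],
            [-1.1, 0.6, -0.3],
        ]
    )
    time = np.array([2.0, 5.0, 3.0, 7.0, 4.0])
    status = np.array([1, 1, 0, 1, 1])
    return SurvivalDataset(X=X, time=time, status=status)


@pytest.fixture
def small_study():
    """Small simulated study with ground truth (p=60, n=120)."""
    cfg = SimulationConfig(p=60, n=120, n_true=6, censor_frac=0.4, seed=7)
    return simulate_study(cfg)


@pytest.fixture
def small_train(small_study):
    data, _ = standardize(small_study.data)
    return data


def fast_pipeline_config(seed=0, **kw):
    """Cheap pipeline settings for small-fixture tests."""
    defaults = dict(
        seed=seed,
        cox_cv_folds=3,
        cox_n_lambdas=15,
        aft_cv_folds=3,
        aft_n_lambdas=10,
        max_outer_rounds=2,
        min_group_labeled=5,
    )
    defaults.update(kw)
    return PipelineConfig(**defaults)


@pytest.fixture
def fast_config():
    return fast_pipeline_config()
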