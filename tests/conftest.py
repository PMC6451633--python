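import numpy as np
import pytest

from frailtymix import EMControl, SimulationConfig, SurvivalDataset, simulate_dataset


@pytest.fixture(scope="session")
def toy_dataset():
    """4 subjects in 2 groups, one covariate, hand-checkable."""
    return SurvivalDataset(
        time=np.array([1.0, 2.0, 2.0, 3.0]),
        status=np.array([1, 1, 0, 1]),
        covariates=np.array([[0.5], [-0.5], [1.0], [0.0]]),
        group_idx=np.array([0, 0, 1, 1]),
        group_labels=np.array(["A", "B"]),
    )


@pytest.fixture(scope="session")
def small_two_pop():
    """Small two-population dataset with clear contrast, plus true labels."""
    cfg = SimulationConfig(J=15, n_j=8, K=2, pi=(0.4, 0.6), w=(1.0, 2.5),
                           beta=(0.4,), seed=7)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def one_pop_dataset():
    cfg = SimulationConfig(J=20, n_j=20, K=1, pi=(1.0,), w=(1.0,), beta=(0.4,), seed=5)
    data, _ = simulate_dataset(cfg)
    return data


@pytest.fixture(scope="session")
def fast_control():
    return EMControl(seed=1, n_restarts=3)
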