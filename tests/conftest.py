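import numpy as np
import pytest

from rtcondep import GeneratingSpec, simulate_dataset
from rtcondep.models import ModelSpec


@pytest.fixture(scope="session")
def ci_dataset():
    """Small conditional-independence dataset with known truth."""
    spec = GeneratingSpec(model=ModelSpec(kind="ci"), n_persons=400, n_items=5)
    ds, truth = simulate_dataset(spec, seed=1234)
    return ds, truth


@pytest.fixture(scope="session")
def linear_dataset():
    """Small linear conditional-dependence dataset with known truth."""
    spec = GeneratingSpec(
        model=ModelSpec(kind="linear"), n_persons=500, n_items=6,
        mu_I=np.array([1.0, 0.0, 0.0, 0.3, 0.5]),
        Sigma_I=np.diag([0.04, 0.04, 0.09, 0.04, 0.04]))
    ds, truth = simulate_dataset(spec, seed=4321)
    return ds, truth
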