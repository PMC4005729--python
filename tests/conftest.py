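import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import nmixsdm as nx

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def small_counts():
    """3 sites x 2 surveys with a numeric and a categorical covariate."""
    counts = np.array([[2.0, 3.0], [0.0, 1.0], [4.0, 2.0]])
    site = pd.DataFrame({"status": ["absent", "present", "absent"],
                         "habitat": ["palm", "building", "palm"]})
    obs = {"cloud": np.array([[10.0, 60.0], [30.0, 80.0], [0.0, 50.0]])}
    return nx.CountData(counts=counts, site_covariates=site, obs_covariates=obs)


@pytest.fixture
def intercept_data():
    """Single-covariate-free data for intercept-only models."""
    rng = np.random.default_rng(7)
    N = rng.poisson(8, size=30)
    y = rng.binomial(N[:, None], 0.6, size=(30, 4)).astype(float)
    return nx.CountData(counts=y, site_covariates=pd.DataFrame(index=range(30)))


@pytest.fixture
def small_env():
    """5 x 6 grid, 2 layers, 30 m cells."""
    rng = np.random.default_rng(11)
    geom = nx.GridGeometry(n_rows=5, n_cols=6, cell_size=30.0)
    layers = {"a": rng.standard_normal((5, 6)), "b": rng.standard_normal((5, 6))}
    return nx.EnvStack(geometry=geom, layers=layers)
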