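import warnings

import numpy as np
import pytest

from fvsdecode import Dataset, SimConfig, SplitConfig, make_split, simulate

warnings.filterwarnings("ignore", module="sklearn")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_regression(rng):
    """20 x 5 regression dataset with y an exact function of f2."""
    X = rng.standard_normal((20, 5))
    y = 3.0 * X[:, 2]
    return Dataset(
        X=X,
        y=y,
        feature_names=[f"f{j}" for j in range(5)],
        task="regression",
    )


@pytest.fixture
def tiny_classification(rng):
    X = rng.standard_normal((40, 4))
    y = (X[:, 1] > 0).astype(int)
    return Dataset(
        X=X,
        y=y,
        feature_names=[f"f{j}" for j in range(4)],
        task="classification",
    )


@pytest.fixture
def sim_regression():
    ds, truth = simulate(SimConfig(n=200, m=12, k=3, effect=3.0, rho=0.2,
                                   noise_sd=0.5, covariate_strength=0.0, seed=7))
    return ds, truth


@pytest.fixture
def sim_classification():
    ds, truth = simulate(SimConfig(n=200, m=12, k=3, effect=3.0, rho=0.2,
                                   noise_sd=0.5, covariate_strength=0.0,
                                   task="classification", seed=7))
    return ds, truth


@pytest.fixture
def split_70(sim_regression):
    ds, _ = sim_regression
    return make_split(ds, SplitConfig(seed=1))


@pytest.fixture
def csv_table(tmp_path):
    path = tmp_path / "table.csv"
    path.write_text(
        "id,f1,f2,TIV,age\n"
        "s1,1.0,0.5,1400,25\n"
        "s2,2.0,0.1,1500,30\n"
        "s3,3.0,0.9,1350,35\n"
        "s4,4.0,0.3,1600,28\n"
    )
    return path
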