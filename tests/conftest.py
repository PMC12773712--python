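import math

import numpy as np
import pytest

import bamscan as bs


@pytest.fixture(scope="session")
def paper_prior() -> bs.PriorSpec:
    """The published study's prior: mu=0.0053, unit-information h=1,
    1,912 candidate variables, 201,917 participants."""
    return bs.PriorSpec(mu=0.0053, h=1.0, nu=1912, n=201917)


@pytest.fixture(scope="session")
def small_data() -> bs.Dataset:
    """Seeded 500 x 3 logistic fixture with one real effect."""
    rng = np.random.default_rng(42)
    X = rng.standard_normal((500, 3))
    eta = -1.0 + 0.9 * X[:, 0]
    y = (rng.random(500) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    return bs.Dataset(X, y)


@pytest.fixture(scope="session")
def block_data() -> tuple[bs.Dataset, bs.PriorSpec]:
    """nu=8 block-correlated cohort (near-duplicate pair + cluster +
    independents) with two true effects; enumerable exactly."""
    cfg = bs.SynthConfig(
        n=1500,
        blocks=(bs.BlockSpec(2, r2=0.81), bs.BlockSpec(3, r2=0.3), bs.BlockSpec(3)),
        effects={0: 0.8, 4: 0.6},
        intercept=math.log(0.15 / 0.85),
        seed=7,
    )
    data, _ = bs.generate_dataset(cfg)
    return data, bs.PriorSpec(1.0 / 7.0, 1.0, 8, data.n)
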