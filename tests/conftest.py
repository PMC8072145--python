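import numpy as np
import pytest

from escprog.synthetic import SyntheticConfig, make_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """In-memory 20-patient test-scale cohort shared across tests."""
    cfg = SyntheticConfig.test_scale(n_patients=20, seed=7)
    records, truth = make_cohort(cfg)
    return cfg, records, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_ball_mask(n: int, radius: float) -> np.ndarray:
    c = (n - 1) / 2.0
    zz, yy, xx = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    return ((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) <= radius**2
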