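import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import movecox as mc

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """One study-sized synthetic cohort, zeros imputed, ready to fit."""
    cfg = mc.SimulationConfig(n_subjects=3319, seed=42)
    df = mc.simulate_cohort(cfg)
    imputed, _ = mc.impute_cohort(df)
    return imputed


@pytest.fixture(scope="session")
def fitted_by_rotation(default_cohort):
    """Fully adjusted fits of the same cohort under the three rotations."""
    return {
        rot: mc.CompositionalCoxPH(
            default_cohort, rotation=rot, covariates="model-2"
        ).fit()
        for rot in mc.Rotation
    }


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    cfg = mc.SimulationConfig(n_subjects=700, seed=7, zero_rate_mvpa=0.0)
    return mc.simulate_cohort(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_compositions(rng: np.random.Generator, n: int, total: float = 960.0):
    """Strictly interior random compositions via Dirichlet draws."""
    props = rng.dirichlet(np.full(3, 2.0), size=n)
    return np.clip(props, 1e-6, None) * total
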