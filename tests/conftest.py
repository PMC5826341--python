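import numpy as np
import pandas as pd
import pytest

from lingadapt import WorldConfig, generate_world


@pytest.fixture(scope="session")
def default_world() -> pd.DataFrame:
    """One default synthetic world (n = 500), shared across read-only tests."""
    return generate_world(WorldConfig(seed=7))


@pytest.fixture(scope="session")
def flat_world() -> pd.DataFrame:
    """World with no clustering, no humidity effect, no borrowing."""
    return generate_world(
        WorldConfig(
            beta_humidity_tone=0.0,
            family_intercept_sd=0.0,
            family_slope_sd=0.0,
            area_intercept_sd=0.0,
            area_slope_sd=0.0,
            seed=11,
        )
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
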