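import numpy as np
import pytest

from tricadence import SeasonGenConfig, gen_season_dataset


@pytest.fixture(scope="session")
def linear_season():
    """Two-season linear-truth dataset also used for external cross-checks."""
    cfg = SeasonGenConfig(
        n_participants=10,
        weeks=tuple(range(12)),
        trend_shape="linear",
        beta0=62.0,
        beta1=0.25,
        beta2=1.5,
        sd_b0=4.0,
        sd_b1=0.2,
        sd_eps=2.0,
        two_season_fraction=0.5,
        seed=9,
    )
    return gen_season_dataset(cfg)


@pytest.fixture(scope="session")
def ushape_season():
    """Mid-season-dip dataset used for smooth-model cross-checks."""
    cfg = SeasonGenConfig(
        n_participants=12,
        weeks=tuple(range(15)),
        trend_shape="u_shape",
        beta0=60.0,
        beta2=2.0,
        trend_amp=5.0,
        sd_b0=4.0,
        sd_b1=0.2,
        sd_eps=2.0,
        two_season_fraction=0.5,
        seed=3,
    )
    return gen_season_dataset(cfg)


@pytest.fixture(scope="session")
def nesting_season():
    """60-observation linear-truth dataset for the penalty-limit check."""
    cfg = SeasonGenConfig(
        n_participants=6,
        weeks=tuple(range(10)),
        trend_shape="linear",
        beta0=60.0,
        beta1=0.3,
        sd_b0=3.0,
        sd_b1=0.1,
        sd_eps=2.0,
        seed=5,
    )
    return gen_season_dataset(cfg)


@pytest.fixture(scope="session")
def ols_points():
    """Six fixed (week, cadence) points for closed-form OLS comparisons."""
    weeks = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
    cadence = np.array([60.2, 61.1, 60.8, 62.0, 62.4, 63.1])
    return weeks, cadence
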