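from datetime import date

import numpy as np
import pandas as pd
import pytest

from thermoguild.synthetic import (
    AgentSpec,
    WorldConfig,
    generate_environment,
)

UTC0 = pd.Timestamp("2015-05-01", tz="UTC")


@pytest.fixture(scope="session")
def small_world():
    """A compact seeded world: 2 months, 4 km square, coarse raster."""
    cfg = WorldConfig(
        extent=(0.0, 0.0, 4000.0, 4000.0),
        raster_resolution=20.0,
        start=date(2015, 5, 1),
        end=date(2015, 6, 30),
        n_habitat_patches=20,
        seed=11,
    )
    env = generate_environment(cfg)
    return cfg, env


@pytest.fixture
def rng():
    return np.random.default_rng(123)


def make_track(times, xy, individual_id="a", species="sp", group_id="g"):
    """Build a minimal fix table from timestamps and coordinates."""
    xy = np.asarray(xy, dtype=float)
    return pd.DataFrame(
        {
            "individual_id": individual_id,
            "species": species,
            "group_id": group_id,
            "timestamp": pd.DatetimeIndex(times, tz=None).tz_localize("UTC")
            if pd.DatetimeIndex(times).tz is None
            else pd.DatetimeIndex(times),
            "x": xy[:, 0],
            "y": xy[:, 1],
        }
    )


@pytest.fixture
def flat_temperature():
    """Daily temperature table over May-Aug 2015 with modest variation."""
    from thermoguild.tracking import prepare_temperatures

    rng = np.random.default_rng(7)
    dates = pd.date_range("2015-05-01", "2015-08-31", freq="D")
    t = pd.DataFrame({"date": dates.date, "t_max": 28 + rng.normal(0, 3, len(dates))})
    return prepare_temperatures(t)
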