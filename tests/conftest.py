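import dataclasses

import numpy as np
import pandas as pd
import pytest

from dispersalkit import simulate as sim


def make_track(times, lons, lats, iid="X1"):
    """Canonical fix frame from parallel lists."""
    return pd.DataFrame(
        {
            "individual_id": iid,
            "t": pd.to_datetime(times, utc=True),
            "lon": np.asarray(lons, dtype=float),
            "lat": np.asarray(lats, dtype=float),
        }
    )


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study with trajectories (shared across tests)."""
    cfg = dataclasses.replace(sim.SimConfig(seed=12345), n_broods=30)
    study = sim.generate_study(cfg)
    sim.generate_tracks(study, cfg)
    return study


@pytest.fixture(scope="session")
def full_study():
    """A default-size synthetic study with trajectories."""
    cfg = sim.SimConfig(seed=2024)
    study = sim.generate_study(cfg)
    sim.generate_tracks(study, cfg)
    return study
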