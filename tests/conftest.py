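import numpy as np
import pandas as pd
import pytest

from vesselbird.simulate import SimConfig, SimDataset


@pytest.fixture(scope="session")
def small_sim() -> SimDataset:
    """A small joint dataset shared by unit tests (4 birds, 2 days)."""
    return SimDataset(SimConfig(n_birds=4, n_vessels=6, days=2.0, seed=11))


@pytest.fixture(scope="session")
def default_sim() -> SimDataset:
    """The default-size dataset used by the detection acceptance checks."""
    return SimDataset(SimConfig(seed=1))


def toy_fixes(bird_id, t0, lats, lons, step_min=5):
    """Helper: a fix DataFrame from coordinate lists at a fixed cadence."""
    t0 = pd.Timestamp(t0)
    return pd.DataFrame({
        "bird_id": bird_id,
        "t": [t0 + pd.Timedelta(minutes=step_min * i) for i in range(len(lats))],
        "lat": list(lats), "lon": list(lons),
    })
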