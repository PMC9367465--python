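import numpy as np
import pandas as pd
import pytest

from mpcva import DyeModelParams, ScenarioConfig


@pytest.fixture
def params():
    return DyeModelParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def control_config():
    return ScenarioConfig(seed=101, n_cells=400, toxin_effect=0.0)


@pytest.fixture
def mixed_config():
    return ScenarioConfig(seed=202, n_cells=400, toxin_effect=0.3)


@pytest.fixture
def fig3_measurements():
    """The worked time-lapse example: a dividing lineage and a lysing cell.

    C1 is measured 4 times and divides at 36 h; its daughters C1.1 and
    C1.2 never divide.  C3 is measured at {0, 9, 24, 36, 48, 56} h and
    observed absent at the 72 h frame.
    """
    rows = []
    for t in (0.0, 12.0, 24.0, 36.0):
        rows.append(("C1", t, 100.0, 50.0))
    for cid in ("C1.1", "C1.2"):
        for t in (48.0, 60.0, 72.0, 80.0):
            rows.append((cid, t, 100.0, 50.0))
    for t in (0.0, 9.0, 24.0, 36.0, 48.0, 56.0):
        rows.append(("C3", t, 150.0, 50.0))
    measurements = pd.DataFrame(
        rows, columns=["cell_id", "time_h", "raw_intensity", "background_intensity"]
    )
    events = pd.DataFrame(
        {
            "cell_id": ["C1", "C1.1", "C1.2", "C3"],
            "division_time": [36.0, np.nan, np.nan, np.nan],
            "lysis_time": [np.nan, np.nan, np.nan, 72.0],
        }
    )
    return measurements, events
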