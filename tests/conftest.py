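import numpy as np
import pandas as pd
import pytest

from firetraits.grid import FireEventRaster, LandscapeSpec


@pytest.fixture
def small_spec():
    return LandscapeSpec(n_rows=4, n_cols=4, cell_size=1.0,
                         window_start=0.0, window_end=22.0, origin=(0.0, 0.0))


@pytest.fixture
def small_raster(small_spec):
    # hand-laid events: cell (0,0) burns at 3 and 10; (0,1) at 5; rest unburnt
    events = pd.DataFrame({
        "row": [0, 0, 0],
        "col": [0, 0, 1],
        "time": [3.0, 10.0, 5.0],
    })
    return FireEventRaster(small_spec, events)


@pytest.fixture
def clean_occurrences_table():
    rng = np.random.default_rng(42)
    n = 40
    return pd.DataFrame({
        "record_id": np.arange(n),
        "species": np.repeat([f"sp{i}" for i in range(4)], n // 4),
        "decimalLongitude": rng.uniform(115.01, 118.0, n),
        "decimalLatitude": rng.uniform(-37.99, -35.0, n),
        "year": rng.integers(1950, 2020, n),
        "basisOfRecord": "HUMAN_OBSERVATION",
        "coordinateUncertaintyInMeters": rng.uniform(10, 500, n).round(0),
        "issue": "",
    })
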