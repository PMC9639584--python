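import numpy as np
import pandas as pd
import pytest

from treeuse.raster import GridRaster

TZ = "UTC+10:00"
T0 = pd.Timestamp("2016-04-01 00:00").tz_localize(TZ)
STEP = pd.Timedelta(hours=4)


def labeled_frame(labels, animal="K1", start=T0, step=STEP):
    """Build a labeled-fix frame from a label sequence (None = no tree)."""
    n = len(labels)
    return pd.DataFrame({
        "animal_id": animal,
        "t": [start + i * step for i in range(n)],
        "x": np.zeros(n),
        "y": np.zeros(n),
        "tree_id": list(labels),
    })


def grid(values, cell_size=1.0, origin=(0.0, 0.0), role="generic"):
    return GridRaster(np.asarray(values, float), cell_size, origin, role)


@pytest.fixture
def toy_trees():
    return pd.DataFrame({
        "tree_id": ["A", "B", "C"],
        "x": [0.0, 100.0, 50.0],
        "y": [0.0, 0.0, 80.0],
        "species": ["E. populnea"] * 3,
        "dbh_cm": [40.0, 60.0, 25.0],
        "height_m": [12.0, 15.0, 8.0],
        "cover": ["medium", "high", "low"],
        "leaf_n_pct": [1.2, 1.8, 0.9],
        "fpc_mg_g": [3.0, 7.5, 1.0],
    })
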