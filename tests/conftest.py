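import numpy as np
import pandas as pd
import pytest

from celldrift import (
    DistanceSeries,
    ObservationSet,
    PopulationSummary,
    WoundGeometry,
)


@pytest.fixture
def axis_wound() -> WoundGeometry:
    """Wound edge along the y axis, tissue at positive x."""
    return WoundGeometry(p1=(0.0, 0.0), p2=(0.0, 1.0), interior_sign=1)


@pytest.fixture
def small_obs() -> ObservationSet:
    return ObservationSet(
        pd.DataFrame(
            {
                "cell_id": ["a", "a", "b"],
                "time_min": [0.0, 10.0, 0.0],
                "x_um": [5.0, 8.0, 12.0],
                "y_um": [1.0, -2.0, 3.0],
                "channel": ["photoconverted"] * 3,
            }
        )
    )


def make_summary(t, mean_dist, mean_sq_dist, n_cells=100) -> PopulationSummary:
    t = np.asarray(t, dtype=float)
    return PopulationSummary(
        pd.DataFrame(
            {
                "time_min": t,
                "n_cells": np.full(t.size, n_cells),
                "mean_dist": np.asarray(mean_dist, dtype=float),
                "mean_sq_dist": np.asarray(mean_sq_dist, dtype=float),
            }
        )
    )


def make_series(cell_ids, times, distances) -> DistanceSeries:
    return DistanceSeries(
        pd.DataFrame(
            {
                "cell_id": cell_ids,
                "time_min": np.asarray(times, dtype=float),
                "distance_um": np.asarray(distances, dtype=float),
            }
        )
    )
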