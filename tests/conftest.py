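import numpy as np
import pandas as pd
import pytest

from aqrep import (
    ConcentrationField,
    GridSpec,
    PopulationRaster,
    ScenarioConfig,
    StationRecord,
    generate_scenario,
)


@pytest.fixture
def grid5():
    return GridSpec(origin_x=0.0, origin_y=0.0, n_cols=5, n_rows=5, dx=45.0, dy=48.0)


@pytest.fixture
def hours24():
    return pd.date_range("2019-06-01", periods=24, freq="h")


@pytest.fixture
def small_scenario():
    """Deterministic 10x10 x 120 h ox-conserved scenario with a mixed network."""
    return generate_scenario(ScenarioConfig(
        seed=11, n_rows=10, n_cols=10, n_hours=120,
        n_general=2, n_roadside=1, n_background=1,
    ))


def homogeneous_field(grid, times, level=30.0, pollutant="NO2"):
    """Spatially flat field whose level varies by hour."""
    series = level * (1.0 + 0.3 * np.sin(np.arange(len(times)) / 5.0))
    values = np.broadcast_to(series[:, None, None], (len(times), *grid.shape)).copy()
    return ConcentrationField(grid=grid, pollutant=pollutant, unit="ug/m3", times=times, values=values)


def uniform_population(grid, per_cell=1.0):
    return PopulationRaster(grid=grid, counts=np.full(grid.shape, per_cell))


def station_at_cell(grid, row, col, sid="S1", stype="general"):
    x = grid.origin_x + (col + 0.5) * grid.dx
    y = grid.origin_y + (row + 0.5) * grid.dy
    return StationRecord(id=sid, station_type=stype, x=x, y=y, cell_index=(row, col))
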