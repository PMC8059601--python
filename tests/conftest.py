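import numpy as np
import pytest
import shapely

from pyrodiv import (
    FireEvent,
    FireRecordSet,
    GridSpec,
    Raster,
    build_trait_stack,
    two_regime_fixture,
)


@pytest.fixture
def small_grid() -> GridSpec:
    """10 x 10 grid of 10 m cells (1 km2 landscape, 0.01 ha cells)."""
    return GridSpec(x_min=0.0, y_max=100.0, cell_size=10.0, nrows=10, ncols=10)


def square_event(
    grid: GridSpec,
    fire_id: str,
    year: int,
    doy: int = 200,
    row0: int = 0,
    col0: int = 0,
    size: int = 4,
    severity: float | np.ndarray = 1.5,
) -> FireEvent:
    """A square fire aligned to grid cells with constant (or given) severity."""
    cell = grid.cell_size
    x0 = grid.x_min + col0 * cell
    y1 = grid.y_max - row0 * cell
    poly = shapely.box(x0, y1 - size * cell, x0 + size * cell, y1)
    sev = np.full(grid.shape, np.nan)
    block = np.broadcast_to(np.asarray(severity, dtype=float), (size, size))
    sev[row0 : row0 + size, col0 : col0 + size] = block
    return FireEvent(
        fire_id=fire_id,
        year=year,
        ignition_doy=doy,
        perimeter=poly,
        severity=Raster(sev, grid),
    )


@pytest.fixture
def make_event(small_grid):
    def _make(**kwargs) -> FireEvent:
        kwargs.setdefault("grid", small_grid)
        return square_event(**kwargs)

    return _make


@pytest.fixture
def simple_records(small_grid) -> FireRecordSet:
    """Two overlapping fires (1990, 2000) on the small grid."""
    events = [
        square_event(small_grid, "a", 1990, doy=150, row0=0, col0=0, size=6, severity=1.0),
        square_event(small_grid, "b", 2000, doy=250, row0=0, col0=0, size=4, severity=2.0),
    ]
    return FireRecordSet(events, 1985, 2018, small_grid)


@pytest.fixture(scope="session")
def regime_landscape():
    """The two-regime landscape, its units and trait stack (built once)."""
    records, units = two_regime_fixture(seed=0)
    stack = build_trait_stack(records)
    return records, units, stack
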