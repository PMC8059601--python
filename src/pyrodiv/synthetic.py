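"""Synthetic fire mosaics and driver tables with known ground truth.

Emulates a national large-fire record at desk scale: Poisson annual
ignitions; lognormal fire sizes; compact-but-irregular perimeters grown by
thresholding a smoothed random field around an ignition point; spatially
correlated CBI severity surfaces in [0, 3]; wrapped-normal ignition dates.
The default landscape uses 1 ha (100 m) cells on a 200 x 200 grid —
40 kha, large enough to hold several >404 ha fires — over the 1985-2018
record window; every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage

from .drivers import ModelSpec, ScalingRecord, simulate_from_model
from .fire_records import FireEvent, FireRecordSet, LandscapeUnit
from .grid import GridSpec, Raster

__all__ = [
    "RegimeParams",
    "simulate_fire_records",
    "two_regime_fixture",
    "simulate_driver_table",
    "SimulatedDrivers",
]


@dataclass
class RegimeParams:
    """Knobs of a synthetic fire regime.

    Fire sizes are lognormal in hectares (defaults give a ~1100 ha median,
    matching the large-fire record's emphasis); severity is a correlated
    Gaussian field rescaled to the given CBI mean/sd; season is a wrapped
    normal around ``season_mean_doy`` with spread ``season_sd_days`` (the
    inverse of a concentration).
    """

    ignition_rate: float = 1.5  # mean fires per year
    size_log_mu: float = 7.0  # ln ha; exp(7) ~ 1100 ha
    size_log_sigma: float = 0.8
    severity_mean: float = 1.6
    severity_sd: float = 0.7
    severity_corr_cells: float = 4.0
    season_mean_doy: float = 213.0  # early August
    season_sd_days: float = 35.0
    record_start: int = 1985
    record_end: int = 2018
    grid: GridSpec = field(
        default_factory=lambda: GridSpec(
            x_min=0.0, y_max=20_000.0, cell_size=100.0, nrows=200, ncols=200
        )
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ignition_rate", "size_log_sigma", "severity_sd",
                     "severity_corr_cells", "season_sd_days"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _wrapped_normal_doy(rng, mean_doy: float, sd_days: float, size: int) -> np.ndarray:
    d = rng.normal(mean_doy, sd_days, size=size)
    return ((np.round(d) - 1) % 365 + 1).astype(int)


def _grow_blob(
    rng, grid: GridSpec, target_cells: int, smooth_sigma: float = 3.0
) -> np.ndarray | None:
    """Connected burn mask of ~target_cells cells (within 5%), or None.

    A smoothed noise field minus a radial ramp from a random ignition cell
    gives compact, irregular superlevel sets; the threshold is searched so
    the component containing the ignition cell hits the target area.
    """
    nr, nc = grid.shape
    r0, c0 = rng.integers(nr), rng.integers(nc)
    noise = ndimage.gaussian_filter(rng.standard_normal((nr, nc)), smooth_sigma)
    noise *= 2.0 / max(noise.std(), 1e-9)
    rr, cc = np.mgrid[0:nr, 0:nc]
    f = noise - np.hypot(rr - r0, cc - c0) / np.sqrt(target_cells / np.pi)
    order = np.argsort(f.ravel())[::-1]
    # 4-connectivity so the cell union is a single edge-connected polygon
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

    def component_size(k: int) -> tuple[np.ndarray, int]:
        mask = np.zeros(nr * nc, dtype=bool)
        mask[order[:k]] = True
        mask = mask.reshape(nr, nc)
        labels, _ = ndimage.label(mask, structure=structure)
        lab0 = labels[r0, c0]
        comp = labels == lab0 if lab0 else np.zeros_like(mask)
        return comp, int(comp.sum())

    lo, hi = target_cells, min(nr * nc, 8 * target_cells)
    for _ in range(30):
        k = (lo + hi) // 2
        comp, size = component_size(k)
        if 0.95 * target_cells <= size <= 1.05 * target_cells:
            return comp
        if size < target_cells:
            lo = k + 1
        else:
            hi = k - 1
        if lo > hi:
            break
    return comp if 0.9 * target_cells <= size <= 1.1 * target_cells else None


def _mask_to_polygon(mask: np.ndarray, grid: GridSpec) -> shapely.Geometry:
    rows, cols = np.nonzero(mask)
    cell = grid.cell_size
    boxes = [
        shapely.box(
            grid.x_min + c * cell,
            grid.y_max - (r + 1) * cell,
            grid.x_min + (c + 1) * cell,
            grid.y_max - r * cell,
        )
        for r, c in zip(rows, cols)
    ]
    return shapely.union_all(boxes)


def _severity_field(rng, shape: tuple[int, int], params: RegimeParams) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), params.severity_corr_cells)
    f = (f - f.mean()) / max(f.std(), 1e-9)
    return np.clip(params.severity_mean + params.severity_sd * f, 0.0, 3.0)


def _crop_raster(data: np.ndarray, mask: np.ndarray, grid: GridSpec, pad: int = 1) -> Raster:
    rows, cols = np.nonzero(mask)
    r0, r1 = max(rows.min() - pad, 0), min(rows.max() + pad + 1, grid.nrows)
    c0, c1 = max(cols.min() - pad, 0), min(cols.max() + pad + 1, grid.ncols)
    sub = GridSpec(
        x_min=grid.x_min + c0 * grid.cell_size,
        y_max=grid.y_max - r0 * grid.cell_size,
        cell_size=grid.cell_size,
        nrows=r1 - r0,
        ncols=c1 - c0,
        crs=grid.crs,
    )
    out = np.where(mask[r0:r1, c0:c1], data[r0:r1, c0:c1], np.nan)
    return Raster(out, sub)


def simulate_fire_records(params: RegimeParams) -> FireRecordSet:
    """Simulate a fire record: per-year Poisson ignitions, blob perimeters
    grown to lognormal target areas, correlated severity fields, wrapped-
    normal ignition dates. A fire that cannot fit the grid is resampled
    (with a warning) at most 10 times, then skipped."""
    rng = np.random.default_rng(params.seed)
    grid = params.grid
    cell_ha = grid.cell_area_ha
    max_cells = grid.nrows * grid.ncols
    events: list[FireEvent] = []
    counter = 0
    for year in range(params.record_start, params.record_end + 1):
        n_fires = rng.poisson(params.ignition_rate)
        if n_fires == 0:
            continue
        doys = _wrapped_normal_doy(rng, params.season_mean_doy, params.season_sd_days, n_fires)
        for i in range(n_fires):
            mask = None
            for attempt in range(10):
                area_ha = rng.lognormal(params.size_log_mu, params.size_log_sigma)
                target = int(round(area_ha / cell_ha))
                if target < 1:
                    target = 1
                if target > 0.5 * max_cells:
                    warnings.warn(
                        f"sampled fire of {area_ha:.0f} ha exceeds half the grid; "
                        "resampling", stacklevel=2,
                    )
                    continue
                mask = _grow_blob(rng, grid, target)
                if mask is not None:
                    break
            if mask is None:
                continue
            counter += 1
            sev = _severity_field(rng, grid.shape, params)
            events.append(
                FireEvent(
                    fire_id=f"f{counter:04d}",
                    year=year,
                    ignition_doy=int(doys[i]),
                    perimeter=_mask_to_polygon(mask, grid),
                    severity=_crop_raster(sev, mask, grid),
                )
            )
    return FireRecordSet(events, params.record_start, params.record_end, grid)


def _square_fire(
    fire_id: str, year: int, doy: int, grid: GridSpec,
    row0: int, col0: int, size: int, severity: np.ndarray,
) -> FireEvent:
    mask = np.zeros(grid.shape, dtype=bool)
    mask[row0 : row0 + size, col0 : col0 + size] = True
    full = np.full(grid.shape, np.nan)
    full[mask] = severity
    return FireEvent(
        fire_id=fire_id,
        year=year,
        ignition_doy=doy,
        perimeter=_mask_to_polygon(mask, grid),
        severity=_crop_raster(np.nan_to_num(full), mask, grid),
    )


def two_regime_fixture(seed: int = 0):
    """A two-regime landscape plus its analysis units.

    The west half burns often at low severity in small patches; the east
    half burns twice at high severity in large patches. Returns
    ``(records, [west_unit, east_unit, union_unit])``. Mixing the regimes
    adds between-regime trait dispersion, so the union's FDis exceeds both
    halves'.
    """
    rng = np.random.default_rng(seed)
    grid = GridSpec(x_min=0.0, y_max=10_000.0, cell_size=100.0, nrows=100, ncols=100)
    events: list[FireEvent] = []
    fid = 0
    # west: every five years the half burns as a grid of small (100 ha)
    # low-severity fires, so each cell's history is near-identical
    tile = 10
    for year in range(1986, 2018, 5):
        doy = int(rng.integers(125, 135))
        for r0 in range(0, grid.nrows, tile):
            for c0 in range(0, 50, tile):
                fid += 1
                sev = np.clip(rng.normal(0.8, 0.15, size=tile * tile), 0.0, 3.0)
                events.append(
                    _square_fire(f"w{fid:03d}", year, doy, grid, r0, c0, tile, sev)
                )
    # east: two rare fires, each one large high-severity patch over the half
    for year, doy in ((1990, 230), (2010, 245)):
        fid += 1
        mask = np.zeros(grid.shape, dtype=bool)
        mask[:, 50:] = True
        sev_full = np.full(grid.shape, np.nan)
        sev_full[mask] = np.clip(rng.normal(2.6, 0.12, size=int(mask.sum())), 0.0, 3.0)
        events.append(
            FireEvent(
                fire_id=f"e{fid:03d}",
                year=year,
                ignition_doy=doy,
                perimeter=_mask_to_polygon(mask, grid),
                severity=_crop_raster(np.nan_to_num(sev_full), mask, grid),
            )
        )
    records = FireRecordSet(events, 1985, 2018, grid)

    west = shapely.box(0.0, 0.0, 5_000.0, 10_000.0)
    east = shapely.box(5_000.0, 0.0, 10_000.0, 10_000.0)
    units = [
        LandscapeUnit("west", west),
        LandscapeUnit("east", east),
        LandscapeUnit("union", shapely.union_all([west, east])),
    ]
    return records, units


@dataclass
class SimulatedDrivers:
    """A simulated driver table with the generative truth alongside."""

    table: pd.DataFrame
    scaling: ScalingRecord
    truth: ModelSpec


def simulate_driver_table(
    spec: ModelSpec, n_units: int, n_groups: int, seed: int
) -> SimulatedDrivers:
    """Simulate a full driver table from the two-stage model.

    Climate/topography/population covariates are drawn standard normal and
    exactly standardized (so the stored truth applies to the columns as
    fitted); ``wild`` is a uniform proportion; groups are assigned
    round-robin. The returned truth equals the input spec field-for-field.
    """
    if not n_units >= n_groups >= 1:
        raise ValueError("need n_units >= n_groups >= 1")
    rng = np.random.default_rng(seed)
    cols = {}
    for name in ("aet", "cwd", "elev", "rough", "pop_den"):
        x = rng.standard_normal(n_units)
        cols[name] = (x - x.mean()) / x.std(ddof=1)
    df = pd.DataFrame(cols)
    df["wild"] = rng.uniform(0.0, 1.0, size=n_units)
    df["unit_id"] = [f"u{i:04d}" for i in range(n_units)]
    df["parent_id"] = [f"g{i % n_groups:02d}" for i in range(n_units)]
    table, scaling = simulate_from_model(spec, df, seed=int(rng.integers(2**31)))
    return SimulatedDrivers(table=table, scaling=scaling, truth=spec)
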