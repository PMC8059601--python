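"""Fire event records: reading, validation, filtering and rasterization.

The record model mirrors national large-fire archives (MTBS-style): fire
perimeter polygons with a burn year and ignition date, plus a per-fire burn
severity surface on the composite burn index (CBI) scale, 0 (unchanged) to
3 (complete above-ground mortality). Perimeters arrive as GeoJSON; severity
surfaces as georeferenced ASCII grids named ``<fire_id>.asc``.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import mapping, shape

from .grid import GridSpec, Raster, read_ascii_grid, write_ascii_grid

log = logging.getLogger(__name__)

__all__ = [
    "FireEvent",
    "FireRecordSet",
    "LandscapeUnit",
    "read_fires",
    "write_fires",
    "read_units",
    "filter_large_fires",
    "filter_units_by_forest",
    "rasterize_event",
]

CBI_MIN, CBI_MAX = 0.0, 3.0


@dataclass
class FireEvent:
    """One fire: perimeter polygon, timing, and its CBI severity raster."""

    fire_id: str
    year: int
    ignition_doy: int
    perimeter: shapely.Geometry
    severity: Raster
    area_ha: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 1 <= self.ignition_doy <= 366:
            raise ValueError(
                f"fire {self.fire_id}: ignition_doy {self.ignition_doy} outside 1-366"
            )
        if self.perimeter.is_empty:
            raise ValueError(f"fire {self.fire_id}: empty perimeter")
        poly_area_ha = self.perimeter.area / 1e4
        if self.area_ha is None:
            self.area_ha = poly_area_ha
        elif poly_area_ha > 0 and abs(self.area_ha - poly_area_ha) > 0.005 * poly_area_ha:
            raise ValueError(
                f"fire {self.fire_id}: declared area {self.area_ha:.1f} ha differs from "
                f"polygon area {poly_area_ha:.1f} ha by more than 0.5%"
            )
        vals = self.severity.data
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < CBI_MIN or finite.max() > CBI_MAX):
            warnings.warn(
                f"fire {self.fire_id}: CBI values outside [0, 3] "
                f"(range {finite.min():.2f}-{finite.max():.2f}); clipping",
                stacklevel=2,
            )
            self.severity = Raster(np.clip(vals, CBI_MIN, CBI_MAX), self.severity.grid)

    @property
    def sort_key(self) -> tuple[int, int, str]:
        return (self.year, self.ignition_doy, self.fire_id)


@dataclass
class FireRecordSet:
    """Chronologically sorted fire events plus the record window and grid."""

    events: list[FireEvent]
    record_start: int
    record_end: int
    grid: GridSpec

    def __post_init__(self) -> None:
        if self.record_start > self.record_end:
            raise ValueError("record_start must not exceed record_end")
        self.events = sorted(self.events, key=lambda e: e.sort_key)
        for ev in self.events:
            if not self.record_start <= ev.year <= self.record_end:
                raise ValueError(
                    f"fire {ev.fire_id}: year {ev.year} outside record window "
                    f"[{self.record_start}, {self.record_end}]"
                )

    def __len__(self) -> int:
        return len(self.events)

    @property
    def record_length(self) -> int:
        """Span of the record in years, ``record_end - record_start``."""
        return self.record_end - self.record_start


@dataclass
class LandscapeUnit:
    """A landscape analysis unit (e.g. a HUC10 watershed polygon).

    ``parent_id`` names the coarser unit it nests within (e.g. its HUC2),
    used as the grouping level of the driver model. ``flammable_mask``, if
    given, restricts the community table to burnable cells.
    """

    unit_id: str
    geometry: shapely.Geometry
    parent_id: str = ""
    forest_fraction: float = 1.0
    flammable_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.geometry.is_empty:
            raise ValueError(f"unit {self.unit_id}: empty geometry")
        if not 0.0 <= self.forest_fraction <= 1.0:
            raise ValueError(f"unit {self.unit_id}: forest_fraction outside [0, 1]")


def _parse_ig_date(raw: object, fire_id: str) -> tuple[int, int]:
    """Parse an ISO-8601 ignition date to (year, day-of-year)."""
    try:
        d = _dt.date.fromisoformat(str(raw))
    except ValueError as exc:
        raise ValueError(f"fire {fire_id}: unparseable ignition date {raw!r}") from exc
    return d.year, d.timetuple().tm_yday


def read_fires(
    perimeter_path: str | Path,
    severity_dir: str | Path,
    record_start: int,
    record_end: int,
    grid: GridSpec | None = None,
) -> FireRecordSet:
    """Read fire perimeters (GeoJSON) and per-fire severity grids.

    Features need properties ``fire_id``, ``year`` and ``ig_date`` (ISO
    date); the severity grid for each fire is ``<severity_dir>/<fire_id>.asc``.
    Events outside ``[record_start, record_end]`` are dropped with a warning;
    a missing severity grid is an error naming the fire.
    """
    severity_dir = Path(severity_dir)
    with open(perimeter_path) as fh:
        fc = json.load(fh)
    if fc.get("type") != "FeatureCollection":
        raise ValueError(f"{perimeter_path}: expected a GeoJSON FeatureCollection")

    events: list[FireEvent] = []
    for feat in fc["features"]:
        props = feat.get("properties", {})
        fire_id = str(props["fire_id"])
        year = int(props["year"])
        _, doy = _parse_ig_date(props["ig_date"], fire_id)
        if not record_start <= year <= record_end:
            warnings.warn(
                f"fire {fire_id}: year {year} outside record window "
                f"[{record_start}, {record_end}]; dropped",
                stacklevel=2,
            )
            continue
        sev_path = severity_dir / f"{fire_id}.asc"
        if not sev_path.exists():
            raise FileNotFoundError(
                f"severity raster missing for fire {fire_id}: {sev_path}"
            )
        geom = shape(feat["geometry"])
        sev = read_ascii_grid(sev_path)
        area = float(props["area_ha"]) if "area_ha" in props else None
        events.append(
            FireEvent(
                fire_id=fire_id,
                year=year,
                ignition_doy=doy,
                perimeter=geom,
                severity=sev,
                area_ha=area,
            )
        )
    if grid is None:
        meta_path = Path(perimeter_path).parent / "grid.json"
        if meta_path.exists():
            with open(meta_path) as fh:
                grid = GridSpec.from_dict(json.load(fh))
        else:
            grid = _bounding_grid(events)
    return FireRecordSet(events, record_start, record_end, grid)


def _bounding_grid(events: list[FireEvent], cell_size: float | None = None) -> GridSpec:
    """Smallest grid covering all event severities (fallback when none given)."""
    if not events:
        raise ValueError("cannot infer a grid from an empty event list")
    cell = cell_size or events[0].severity.grid.cell_size
    x0 = min(e.severity.grid.x_min for e in events)
    y1 = max(e.severity.grid.y_max for e in events)
    x1 = max(e.severity.grid.x_max for e in events)
    y0 = min(e.severity.grid.y_min for e in events)
    return GridSpec(
        x_min=x0,
        y_max=y1,
        cell_size=cell,
        nrows=int(np.ceil((y1 - y0) / cell)),
        ncols=int(np.ceil((x1 - x0) / cell)),
        crs=events[0].severity.grid.crs,
    )


def write_fires(records: FireRecordSet, out_dir: str | Path) -> None:
    """Write a record set as ``perimeters.geojson`` + ``severity/*.asc``.

    The layout round-trips through :func:`read_fires`; ignition dates are
    reconstructed from (year, day-of-year).
    """
    out_dir = Path(out_dir)
    (out_dir / "severity").mkdir(parents=True, exist_ok=True)
    feats = []
    for ev in records.events:
        date = _dt.date(ev.year, 1, 1) + _dt.timedelta(days=ev.ignition_doy - 1)
        feats.append(
            {
                "type": "Feature",
                "geometry": mapping(ev.perimeter),
                "properties": {
                    "fire_id": ev.fire_id,
                    "year": ev.year,
                    "ig_date": date.isoformat(),
                    "area_ha": ev.area_ha,
                },
            }
        )
        write_ascii_grid(out_dir / "severity" / f"{ev.fire_id}.asc", ev.severity)
    with open(out_dir / "perimeters.geojson", "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
    with open(out_dir / "grid.json", "w") as fh:
        json.dump(records.grid.to_dict(), fh)
    with open(out_dir / "window.json", "w") as fh:
        json.dump({"record_start": records.record_start, "record_end": records.record_end}, fh)


def read_fire_dir(records_dir: str | Path, grid: GridSpec | None = None) -> FireRecordSet:
    """Read a directory produced by :func:`write_fires`."""
    records_dir = Path(records_dir)
    with open(records_dir / "window.json") as fh:
        window = json.load(fh)
    return read_fires(
        records_dir / "perimeters.geojson",
        records_dir / "severity",
        window["record_start"],
        window["record_end"],
        grid=grid,
    )


def read_units(path: str | Path) -> list[LandscapeUnit]:
    """Read landscape units from GeoJSON (``unit_id``; optional ``parent_id``,
    ``forest_fraction`` properties)."""
    with open(path) as fh:
        fc = json.load(fh)
    units = []
    for feat in fc["features"]:
        props = feat.get("properties", {})
        units.append(
            LandscapeUnit(
                unit_id=str(props["unit_id"]),
                geometry=shape(feat["geometry"]),
                parent_id=str(props.get("parent_id", "")),
                forest_fraction=float(props.get("forest_fraction", 1.0)),
            )
        )
    return units


def filter_large_fires(records: FireRecordSet, min_area_ha: float = 404.0) -> FireRecordSet:
    """Keep events strictly larger than ``min_area_ha`` (default 404 ha,
    the large-fire threshold of the national record)."""
    if min_area_ha < 0:
        raise ValueError("min_area_ha must be non-negative")
    kept = [e for e in records.events if e.area_ha > min_area_ha]
    dropped = len(records.events) - len(kept)
    if dropped:
        log.info("filter_large_fires: dropped %d of %d events (<= %.0f ha)",
                 dropped, len(records.events), min_area_ha)
    return replace(records, events=kept)


def filter_units_by_forest(
    units: list[LandscapeUnit], min_fraction: float = 0.5
) -> list[LandscapeUnit]:
    """Drop units with forest cover below ``min_fraction`` (strict ``<``)."""
    kept = [u for u in units if u.forest_fraction >= min_fraction]
    if not kept and units:
        warnings.warn("all units fall below the forest-cover threshold", stacklevel=2)
    return kept


def rasterize_event(event: FireEvent, grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize one event onto ``grid``.

    Returns ``(burn_mask, severity_grid)``: the mask is True for cells whose
    centers fall inside the perimeter; severity is resampled by nearest
    neighbour and NaN outside the mask.
    """
    mask = grid.mask_polygon(event.perimeter)
    if not mask.any():
        warnings.warn(
            f"fire {event.fire_id}: perimeter does not cover any cell center",
            stacklevel=2,
        )
        return mask, np.full(grid.shape, np.nan)
    sev = event.severity.resample_nearest(grid).data
    sev = np.where(mask, sev, np.nan)
    # cells inside the perimeter but off the severity raster: treat as CBI 0
    hole = mask & np.isnan(sev)
    if hole.any():
        sev[hole] = 0.0
    return mask, sev
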