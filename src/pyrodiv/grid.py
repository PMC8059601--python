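"""Lightweight raster grid support.

A :class:`GridSpec` describes a north-up, square-cell analysis grid in a
projected (metric) coordinate system; a :class:`Raster` pairs a data array
with its grid. Rasters are stored on disk as ESRI ASCII grids (``.asc``),
a plain-text georeferenced format readable by any GIS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely

__all__ = ["GridSpec", "Raster", "read_ascii_grid", "write_ascii_grid"]

#: value written for missing cells in .asc files
DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """North-up square-cell grid in a projected CRS with metric units.

    ``x_min``/``y_max`` locate the outer corner of the top-left cell; rows
    increase southward. ``crs`` is an informal tag (e.g. ``"EPSG:5070"`` or
    ``"local-metric"``); geometries are assumed to already share it.
    """

    x_min: float
    y_max: float
    cell_size: float
    nrows: int
    ncols: int
    crs: str = "local-metric"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def x_max(self) -> float:
        return self.x_min + self.ncols * self.cell_size

    @property
    def y_min(self) -> float:
        return self.y_max - self.nrows * self.cell_size

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size**2 / 1e4

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(xs, ys) arrays of shape ``(nrows, ncols)`` with cell-center coords."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        xs = self.x_min + (cols + 0.5) * self.cell_size
        ys = self.y_max - (rows + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing points (no bounds check)."""
        col = np.floor((np.asarray(x) - self.x_min) / self.cell_size).astype(int)
        row = np.floor((self.y_max - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def mask_polygon(self, geom: shapely.Geometry) -> np.ndarray:
        """Boolean mask of cells whose *centers* fall inside ``geom``.

        Cell-center membership is the standard convention for 30 m burn
        products; it makes rasterization deterministic and area-consistent.
        """
        xs, ys = self.cell_centers()
        return shapely.contains_xy(geom, xs.ravel(), ys.ravel()).reshape(self.shape)

    def mask_disc(self, x: float, y: float, radius_m: float) -> np.ndarray:
        xs, ys = self.cell_centers()
        return (xs - x) ** 2 + (ys - y) ** 2 <= radius_m**2

    def same_geometry(self, other: "GridSpec", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.x_min, other.x_min, abs_tol=tol)
            and math.isclose(self.y_max, other.y_max, abs_tol=tol)
            and math.isclose(self.cell_size, other.cell_size, rel_tol=1e-9)
        )

    def to_dict(self) -> dict:
        return {
            "x_min": self.x_min,
            "y_max": self.y_max,
            "cell_size": self.cell_size,
            "nrows": self.nrows,
            "ncols": self.ncols,
            "crs": self.crs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(**d)


@dataclass
class Raster:
    """A single-band float raster on a :class:`GridSpec`; NaN marks no-data."""

    data: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )

    def resample_nearest(self, target: GridSpec) -> "Raster":
        """Nearest-neighbour resampling onto ``target``; NaN outside coverage."""
        xs, ys = target.cell_centers()
        row, col = self.grid.index_of(xs, ys)
        inside = (row >= 0) & (row < self.grid.nrows) & (col >= 0) & (col < self.grid.ncols)
        out = np.full(target.shape, np.nan)
        out[inside] = self.data[row[inside], col[inside]]
        return Raster(out, target)


def write_ascii_grid(path: str | Path, raster: Raster, nodata: float = DEFAULT_NODATA) -> None:
    g = raster.grid
    data = np.where(np.isnan(raster.data), nodata, raster.data)
    header = (
        f"ncols {int(g.ncols)}\n"
        f"nrows {int(g.nrows)}\n"
        f"xllcorner {float(g.x_min)!r}\n"
        f"yllcorner {float(g.y_min)!r}\n"
        f"cellsize {float(g.cell_size)!r}\n"
        f"NODATA_value {float(nodata)!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt="%.6g")


def read_ascii_grid(path: str | Path, crs: str = "local-metric") -> Raster:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(nrows, ncols)
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    data = np.where(data == nodata, np.nan, data)
    cell = header["cellsize"]
    grid = GridSpec(
        x_min=header["xllcorner"],
        y_max=header["yllcorner"] + nrows * cell,
        cell_size=cell,
        nrows=nrows,
        ncols=ncols,
        crs=crs,
    )
    return Raster(data, grid)
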