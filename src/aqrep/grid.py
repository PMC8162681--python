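"""Analysis grid, rasterization of model-output point meshes, and population resampling.

The analysis grid is a regular raster in projected planar metres. Cells are
half-open ``[x0, x0 + dx) x [y0, y0 + dy)`` rectangles indexed 0-based as
``(row, col)`` with row 0 at the grid's minimum y. Dispersion-model output
arrives as an irregular ("dynamic") point mesh that is denser near sources;
each cell's hourly concentration is the arithmetic mean of the mesh points it
contains. Monitoring stations are snapped to the cell containing their
coordinates ("pseudo-stations"), and a coarse population raster is resampled
onto the analysis grid conserving the domain total.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "PointMesh",
    "ConcentrationField",
    "StationRecord",
    "PopulationRaster",
    "rasterize_mesh",
    "locate_pseudo_stations",
    "resample_population",
]

POLLUTANTS = ("PM10", "PM2.5", "NO2", "O3")


@dataclass(frozen=True)
class GridSpec:
    """Regular raster grid in a projected coordinate reference system.

    Parameters
    ----------
    origin_x, origin_y : float
        Coordinates of the grid's lower-left corner (minimum x/y), metres.
    n_cols, n_rows : int
        Grid dimensions; total cell count is ``n_cols * n_rows``.
    dx, dy : float
        Cell size in metres. Defaults follow the 45 m x 48 m street-scale
        raster used for territory-wide exposure mapping.
    crs_id : str
        Identifier of the projected CRS; only checked for equality.
    """

    origin_x: float
    origin_y: float
    n_cols: int
    n_rows: int
    dx: float = 45.0
    dy: float = 48.0
    crs_id: str = "local-metric"

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError(f"cell size must be positive, got dx={self.dx}, dy={self.dy}")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one row and one column")

    @property
    def cell_area_m2(self) -> float:
        return self.dx * self.dy

    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def x_max(self) -> float:
        return self.origin_x + self.n_cols * self.dx

    @property
    def y_max(self) -> float:
        return self.origin_y + self.n_rows * self.dy

    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.n_cols) + 0.5) * self.dx

    def y_centers(self) -> np.ndarray:
        return self.origin_y + (np.arange(self.n_rows) + 0.5) * self.dy

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) cell-center coordinate arrays of shape (n_rows, n_cols)."""
        return np.meshgrid(self.x_centers(), self.y_centers())

    def cell_index(self, x, y):
        """Map coordinates to (row, col) under half-open cell extents.

        Points exactly on a shared edge belong to the upper (larger-index)
        neighbour in floor arithmetic, i.e. the cell whose half-open interval
        contains them; the lower/left cell owns its own lower/left edge.
        Out-of-domain points yield index -1.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.dx).astype(int)
        row = np.floor((y - self.origin_y) / self.dy).astype(int)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        col = np.where(inside, col, -1)
        row = np.where(inside, row, -1)
        return row, col

    def compatible(self, other: "GridSpec") -> bool:
        return self == other


@dataclass
class PointMesh:
    """Irregular model-output point mesh with hourly values per pollutant.

    ``values[pollutant]`` has shape ``(n_points, n_times)``.
    """

    x: np.ndarray
    y: np.ndarray
    times: pd.DatetimeIndex
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        bad = ~(np.isfinite(self.x) & np.isfinite(self.y))
        if bad.any():
            raise ValueError(f"non-finite coordinates at point indices {np.flatnonzero(bad).tolist()}")
        self.times = pd.DatetimeIndex(self.times)
        if len(self.times) > 1 and not self.times.is_monotonic_increasing:
            raise ValueError("timestamps must be strictly increasing")
        for p, v in self.values.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (self.x.size, len(self.times)):
                raise ValueError(f"values[{p!r}] must have shape (n_points, n_times)")
            self.values[p] = v

    @property
    def n_points(self) -> int:
        return self.x.size


@dataclass
class ConcentrationField:
    """Hourly concentrations of one pollutant on the analysis grid.

    ``values`` has shape ``(n_times, n_rows, n_cols)``; missing cells/hours
    are NaN, and ``mask`` exposes the boolean present/missing view.
    """

    grid: GridSpec
    pollutant: str
    unit: str
    times: pd.DatetimeIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.times), self.grid.n_rows, self.grid.n_cols)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != (time, row, col) {expected}")
        with np.errstate(invalid="ignore"):
            if np.any(self.values < 0):
                raise ValueError(f"negative concentrations in {self.pollutant} field")

    @property
    def mask(self) -> np.ndarray:
        """True where a value is present."""
        return np.isfinite(self.values)

    def series_at(self, row: int, col: int) -> np.ndarray:
        return self.values[:, row, col]


@dataclass
class StationRecord:
    """A fixed-site monitor and, once located, its pseudo-station grid cell."""

    id: str
    station_type: str  # general | roadside | background
    x: float
    y: float
    inlet_height: float = 0.0
    cell_index: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.station_type not in ("general", "roadside", "background"):
            raise ValueError(f"unknown station type {self.station_type!r} for station {self.id}")
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"station {self.id} has non-finite coordinates")


@dataclass
class PopulationRaster:
    """Persons per cell on a grid."""

    grid: GridSpec
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != self.grid.shape:
            raise ValueError(f"counts shape {self.counts.shape} != grid shape {self.grid.shape}")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("population counts must be finite")
        if np.any(self.counts < 0):
            raise ValueError("population counts must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def rasterize_mesh(mesh: PointMesh, grid: GridSpec, pollutant: str) -> ConcentrationField:
    """Average mesh-point values into grid cells, hour by hour.

    Each cell's value at each timestep is the arithmetic mean of the values
    at the mesh points falling inside the cell; cells containing no point are
    missing (NaN) at all timesteps.
    """
    if mesh.n_points == 0:
        raise ValueError("mesh contains no points")
    if pollutant not in mesh.values:
        raise KeyError(f"mesh has no values for pollutant {pollutant!r}")
    row, col = grid.cell_index(mesh.x, mesh.y)
    inside = row >= 0
    if not inside.any():
        raise ValueError("mesh has no points inside the grid domain")

    flat = row[inside] * grid.n_cols + col[inside]
    vals = mesh.values[pollutant][inside]  # (n_inside, n_times)
    nt = len(mesh.times)

    sums = np.zeros((grid.n_cells, nt))
    np.add.at(sums, flat, vals)
    counts = np.bincount(flat, minlength=grid.n_cells).astype(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts[:, None]
    means[counts == 0] = np.nan

    values = means.reshape(grid.n_rows, grid.n_cols, nt).transpose(2, 0, 1)
    return ConcentrationField(grid=grid, pollutant=pollutant, unit="ug/m3", times=mesh.times, values=values)


def locate_pseudo_stations(stations: list[StationRecord], grid: GridSpec) -> list[StationRecord]:
    """Snap each station to the grid cell containing it.

    Stations outside the grid are dropped with a warning. Duplicate ids are
    an error. The input records are not modified.
    """
    ids = [s.id for s in stations]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate station ids: {dupes}")
    located: list[StationRecord] = []
    for s in stations:
        row, col = grid.cell_index(s.x, s.y)
        if row < 0:
            warnings.warn(f"station {s.id} at ({s.x}, {s.y}) is outside the grid; excluded", stacklevel=2)
            continue
        located.append(replace(s, cell_index=(int(row), int(col))))
    return located


def resample_population(coarse: PopulationRaster, fine_grid: GridSpec) -> PopulationRaster:
    """Resample a coarse population raster onto a finer analysis grid.

    Each fine cell is assigned to the coarse cell whose center is nearest to
    its own center (nearest-neighbour), and each coarse cell's count is split
    equally among the fine cells assigned to it, so the domain total is
    conserved.
    """
    cg = coarse.grid
    if cg.crs_id != fine_grid.crs_id:
        raise ValueError(f"CRS mismatch: {cg.crs_id!r} vs {fine_grid.crs_id!r}")
    if (cg.x_max <= fine_grid.origin_x or fine_grid.x_max <= cg.origin_x
            or cg.y_max <= fine_grid.origin_y or fine_grid.y_max <= cg.origin_y):
        raise ValueError("coarse and fine grid extents are disjoint")
    if cg == fine_grid:
        return PopulationRaster(grid=fine_grid, counts=coarse.counts.copy())

    # nearest coarse center along each axis independently (grids are axis-aligned)
    fx, fy = fine_grid.x_centers(), fine_grid.y_centers()
    cx, cy = cg.x_centers(), cg.y_centers()
    jx = np.abs(fx[:, None] - cx[None, :]).argmin(axis=1)  # (n_fine_cols,)
    jy = np.abs(fy[:, None] - cy[None, :]).argmin(axis=1)  # (n_fine_rows,)

    flat = jy[:, None] * cg.n_cols + jx[None, :]  # (fine_rows, fine_cols) coarse flat index
    n_children = np.bincount(flat.ravel(), minlength=cg.n_cells).astype(float)
    share = coarse.counts.ravel() / np.where(n_children > 0, n_children, 1.0)
    counts = share[flat]
    return PopulationRaster(grid=fine_grid, counts=counts)
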