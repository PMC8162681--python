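"""File interfaces: CSV point meshes and station tables, NetCDF rasters,
GeoJSON districts, YAML run configuration.

Gridded fields travel as NetCDF (dims ``time, row, col``) with the grid
geometry in global attributes; point meshes and tabular outputs are plain
CSV. District polygons are GeoJSON with a ``name`` property per feature.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml
from shapely.geometry import mapping, shape

from .grid import ConcentrationField, GridSpec, PointMesh, PopulationRaster, StationRecord
from .similarity import SFMap

__all__ = [
    "read_mesh_csv", "write_mesh_csv",
    "read_stations_csv", "write_stations_csv",
    "read_field_netcdf", "write_field_netcdf",
    "read_population_netcdf", "write_population_netcdf",
    "read_districts_geojson", "write_districts_geojson",
    "write_sf_maps_csv", "load_config",
]

_GRID_ATTRS = ("origin_x", "origin_y", "dx", "dy", "n_cols", "n_rows", "crs_id")


def _grid_to_attrs(grid: GridSpec) -> dict:
    return {a: getattr(grid, a) for a in _GRID_ATTRS}


def _grid_from_attrs(attrs) -> GridSpec:
    kw = {a: attrs[a] for a in _GRID_ATTRS}
    kw["n_cols"] = int(kw["n_cols"])
    kw["n_rows"] = int(kw["n_rows"])
    return GridSpec(**kw)


def read_mesh_csv(path) -> PointMesh:
    """Long-format mesh CSV: columns x, y, pollutant, timestamp, value.

    Rows sharing (x, y) are one mesh point; every point must report every
    pollutant at every timestamp (missing combinations become NaN).
    """
    df = pd.read_csv(path, parse_dates=["timestamp"])
    required = {"x", "y", "pollutant", "timestamp", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mesh CSV {path} lacks columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"mesh CSV {path} is empty")
    points = df[["x", "y"]].drop_duplicates().reset_index(drop=True)
    point_id = pd.MultiIndex.from_frame(points)
    times = pd.DatetimeIndex(sorted(df["timestamp"].unique()))
    values = {}
    for pollutant, sub in df.groupby("pollutant"):
        pivot = sub.pivot_table(index=["x", "y"], columns="timestamp", values="value")
        pivot = pivot.reindex(index=point_id, columns=times)
        values[str(pollutant)] = pivot.to_numpy()
    return PointMesh(x=points["x"].to_numpy(), y=points["y"].to_numpy(), times=times, values=values)


def write_mesh_csv(mesh: PointMesh, path) -> None:
    rows = []
    for pollutant, vals in mesh.values.items():
        for i in range(mesh.n_points):
            for j, t in enumerate(mesh.times):
                rows.append((mesh.x[i], mesh.y[i], pollutant, t.isoformat(), vals[i, j]))
    pd.DataFrame(rows, columns=["x", "y", "pollutant", "timestamp", "value"]).to_csv(path, index=False)


def read_stations_csv(path) -> list[StationRecord]:
    df = pd.read_csv(path)
    required = {"id", "type", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"station CSV {path} lacks columns {sorted(missing)}")
    return [
        StationRecord(
            id=str(row["id"]), station_type=str(row["type"]),
            x=float(row["x"]), y=float(row["y"]),
            inlet_height=float(row.get("inlet_height_m", 0.0) or 0.0),
        )
        for _, row in df.iterrows()
    ]


def write_stations_csv(stations: list[StationRecord], path) -> None:
    pd.DataFrame(
        [(s.id, s.station_type, s.x, s.y, s.inlet_height) for s in stations],
        columns=["id", "type", "x", "y", "inlet_height_m"],
    ).to_csv(path, index=False)


def write_field_netcdf(fld: ConcentrationField, path) -> None:
    ds = xr.Dataset(
        {"concentration": (("time", "row", "col"), fld.values)},
        coords={"time": fld.times},
        attrs={**_grid_to_attrs(fld.grid), "pollutant": fld.pollutant, "unit": fld.unit},
    )
    ds.to_netcdf(path)


def read_field_netcdf(path) -> ConcentrationField:
    with xr.open_dataset(path) as ds:
        grid = _grid_from_attrs(ds.attrs)
        return ConcentrationField(
            grid=grid, pollutant=str(ds.attrs["pollutant"]), unit=str(ds.attrs["unit"]),
            times=pd.DatetimeIndex(ds["time"].values), values=ds["concentration"].values.copy(),
        )


def write_population_netcdf(pop: PopulationRaster, path) -> None:
    ds = xr.Dataset(
        {"population": (("row", "col"), pop.counts)},
        attrs=_grid_to_attrs(pop.grid),
    )
    ds.to_netcdf(path)


def read_population_netcdf(path) -> PopulationRaster:
    with xr.open_dataset(path) as ds:
        return PopulationRaster(grid=_grid_from_attrs(ds.attrs), counts=ds["population"].values.copy())


def read_districts_geojson(path):
    """Read district polygons; returns list of (name, shapely geometry)."""
    with open(path) as fh:
        gj = json.load(fh)
    out = []
    for feat in gj.get("features", []):
        name = feat.get("properties", {}).get("name")
        if name is None:
            raise ValueError(f"district feature without a 'name' property in {path}")
        out.append((str(name), shape(feat["geometry"])))
    if not out:
        raise ValueError(f"no district features in {path}")
    return out


def write_districts_geojson(districts, path) -> None:
    """Write (name, shapely geometry) pairs as a GeoJSON FeatureCollection."""
    features = [
        {"type": "Feature", "properties": {"name": name}, "geometry": mapping(geom)}
        for name, geom in districts
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def write_sf_maps_csv(sf_maps: list[SFMap], path, period: str = "annual") -> None:
    """Long-format SF table: station_id, pollutant, period, row, col, sf, n_valid."""
    frames = []
    for m in sf_maps:
        nr, nc = m.grid.shape
        rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
        frames.append(pd.DataFrame({
            "station_id": m.station_id, "pollutant": m.pollutant, "period": period,
            "row": rows.ravel(), "col": cols.ravel(),
            "sf": m.values.ravel(), "n_valid": m.n_valid.ravel(),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg
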