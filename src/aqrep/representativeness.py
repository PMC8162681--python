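"""Network representativeness maps, represented area/population, and PHNI.

A cell's representativeness by the monitoring network is the best SF it
achieves against any pseudo-station (elementwise max over the per-station SF
maps). The population-health network representation index (PHNI) is the
population-weighted mean of that map over a target domain:

    PHNI_d = sum_{i in d} R_i * pop_i / sum_{i in d} pop_i

so PHNI is 1 when the network tracks every inhabited cell's risk series and
falls toward 0 where populated cells are unrepresented. Station-level
summaries tally the area and population of well-represented cells
(SF > 0.9 by default), and districts get their own PHNI by assigning each
cell to the polygon containing its center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

try:  # vectorized point-in-polygon; shapely >= 2
    from shapely import contains_xy as _contains_xy
except ImportError:  # pragma: no cover
    _contains_xy = None

from .grid import GridSpec, PopulationRaster
from .similarity import SFMap

__all__ = [
    "RepresentativenessMap",
    "DomainMask",
    "PHNIResult",
    "StationSummary",
    "network_representativeness",
    "represented_area",
    "represented_population",
    "phni",
    "seasonal_periods",
    "district_phni",
    "area_population_correlation",
]

SEASON_MONTHS = {
    "spring": (3, 4, 5),
    "summer": (6, 7, 8),
    "autumn": (9, 10, 11),
    "winter": (12, 1, 2),
}


@dataclass
class RepresentativenessMap:
    """Per-cell network representativeness R = max over stations of SF."""

    grid: GridSpec
    values: np.ndarray
    pollutant: str = ""
    period: str = "annual"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("R map must match the grid shape")


@dataclass
class DomainMask:
    """Named boolean cell selection (a district or other target domain)."""

    name: str
    cells: np.ndarray

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=bool)
        if not self.cells.any():
            raise ValueError(f"domain {self.name!r} selects no cells")


@dataclass
class PHNIResult:
    pollutant: str
    domain: str
    period: str
    phni: float
    population_covered: float

    def __post_init__(self) -> None:
        if np.isfinite(self.phni) and not (-1e-12 <= self.phni <= 1 + 1e-12):
            raise ValueError(f"PHNI out of [0, 1]: {self.phni}")


@dataclass
class StationSummary:
    station_id: str
    pollutant: str
    period: str
    represented_area_km2: float
    represented_population: float


def network_representativeness(sf_maps: list[SFMap]) -> RepresentativenessMap:
    """Elementwise max of per-station SF maps; NaN where all are undefined."""
    if not sf_maps:
        raise ValueError("need at least one SF map")
    grid = sf_maps[0].grid
    for m in sf_maps[1:]:
        if m.grid != grid:
            raise ValueError("SF maps must share one grid")
    stack = np.stack([m.values for m in sf_maps])
    with np.errstate(invalid="ignore"):
        r = np.full(grid.shape, np.nan)
        any_def = np.isfinite(stack).any(axis=0)
        r[any_def] = np.nanmax(stack[:, any_def], axis=0)
    return RepresentativenessMap(
        grid=grid, values=r,
        pollutant=sf_maps[0].pollutant, period=sf_maps[0].period,
    )


def represented_area(sf: SFMap | RepresentativenessMap, cutoff: float = 0.9) -> float:
    """Total area (km2) of cells with SF strictly above the cutoff."""
    if not 0 < cutoff < 1:
        raise ValueError(f"cutoff must lie in (0, 1), got {cutoff}")
    with np.errstate(invalid="ignore"):
        n = int((sf.values > cutoff).sum())
    return n * sf.grid.cell_area_m2 / 1e6


def represented_population(
    sf: SFMap | RepresentativenessMap, pop: PopulationRaster, cutoff: float = 0.9
) -> float:
    """Persons living in cells with SF strictly above the cutoff."""
    if not 0 < cutoff < 1:
        raise ValueError(f"cutoff must lie in (0, 1), got {cutoff}")
    if pop.grid != sf.grid:
        raise ValueError("population raster and SF map must share one grid")
    with np.errstate(invalid="ignore"):
        qual = sf.values > cutoff
    return float(pop.counts[qual].sum())


def phni(
    r_map: RepresentativenessMap,
    pop: PopulationRaster,
    domain: DomainMask | None = None,
) -> PHNIResult:
    """Population-weighted mean of R over a domain (whole grid when None).

    Cells whose R is undefined contribute to neither sum; a domain with zero
    population is an error.
    """
    if pop.grid != r_map.grid:
        raise ValueError("population raster and R map must share one grid")
    sel = np.ones(r_map.grid.shape, dtype=bool) if domain is None else domain.cells
    name = "all" if domain is None else domain.name
    if float(pop.counts[sel].sum()) == 0.0:
        raise ValueError(f"domain {name!r} has zero population")
    defined = sel & np.isfinite(r_map.values)
    w = pop.counts[defined]
    wsum = float(w.sum())
    value = float((r_map.values[defined] * w).sum() / wsum) if wsum > 0 else float("nan")
    return PHNIResult(
        pollutant=r_map.pollutant, domain=name, period=r_map.period,
        phni=value, population_covered=wsum,
    )


def seasonal_periods(time_axis) -> dict[str, np.ndarray]:
    """Annual + four season boolean masks over an hourly single-year axis.

    Seasons are calendar-month blocks (spring Mar-May, summer Jun-Aug,
    autumn Sep-Nov, winter Dec-Feb); within one year, winter collects that
    year's January, February and December. Multi-year input is rejected so
    the analysis year is always explicit.
    """
    times = pd.DatetimeIndex(time_axis)
    years = times.year.unique()
    if len(years) > 1:
        raise ValueError(f"time axis spans multiple years {sorted(years)}; select one year first")
    month = times.month.to_numpy()
    masks: dict[str, np.ndarray] = {"annual": np.ones(len(times), dtype=bool)}
    for season, months in SEASON_MONTHS.items():
        masks[season] = np.isin(month, months)
    return masks


def district_phni(
    r_map: RepresentativenessMap,
    pop: PopulationRaster,
    districts,
) -> list[PHNIResult]:
    """One PHNI per district polygon; membership by cell-center containment.

    ``districts`` is a list of ``(name, shapely polygon)`` pairs or
    ``DomainMask`` objects. A district whose cells hold no population is
    reported with NaN PHNI rather than raising.
    """
    results = []
    for d in districts:
        if isinstance(d, DomainMask):
            mask = d
        else:
            name, geom = d
            xs, ys = r_map.grid.center_mesh()
            if _contains_xy is not None:
                cells = _contains_xy(geom, xs, ys)
            else:  # pragma: no cover
                from shapely.geometry import Point
                cells = np.array([[geom.contains(Point(x, y)) for x, y in zip(rx, ry)]
                                  for rx, ry in zip(xs, ys)])
            if not cells.any():
                results.append(PHNIResult(r_map.pollutant, name, r_map.period, float("nan"), 0.0))
                continue
            mask = DomainMask(name=name, cells=cells)
        try:
            results.append(phni(r_map, pop, mask))
        except ValueError:
            results.append(PHNIResult(r_map.pollutant, mask.name, r_map.period, float("nan"), 0.0))
    return results


def quadrant_districts(grid: GridSpec) -> list[DomainMask]:
    """Partition the grid into four quadrant domains (SW, SE, NW, NE)."""
    half_r, half_c = grid.n_rows // 2, grid.n_cols // 2
    rows = np.arange(grid.n_rows)[:, None]
    cols = np.arange(grid.n_cols)[None, :]
    return [
        DomainMask("SW", (rows < half_r) & (cols < half_c)),
        DomainMask("SE", (rows < half_r) & (cols >= half_c)),
        DomainMask("NW", (rows >= half_r) & (cols < half_c)),
        DomainMask("NE", (rows >= half_r) & (cols >= half_c)),
    ]


def area_population_correlation(
    summaries: list[StationSummary], exclude: tuple[str, ...] = ()
) -> tuple[float, float]:
    """Pearson r (and two-sided p) between represented area and population.

    ``exclude`` drops stations by id before the correlation (e.g. a remote
    background site that dominates area but not population). Zero variance
    in either vector yields (nan, nan).
    """
    kept = [s for s in summaries if s.station_id not in exclude]
    if len(kept) < 3:
        raise ValueError("need at least 3 stations for a correlation")
    area = np.array([s.represented_area_km2 for s in kept])
    popn = np.array([s.represented_population for s in kept])
    if np.ptp(area) == 0 or np.ptp(popn) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(area, popn)
    return float(r), float(p)
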