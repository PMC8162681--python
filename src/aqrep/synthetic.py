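"""Synthetic scenarios with the spatiotemporal structure real urban air has.

The generator builds, on a small analysis grid, the ingredients the
representativeness pipeline is sensitive to:

* a spatially near-homogeneous regional background per pollutant with AR(1)
  hourly persistence (regional transport dominates PM, which is why PM risk
  is widely represented);
* localized source plumes decaying exponentially with distance from point or
  line sources, with a diurnal traffic-like modulation (street-scale NO2
  heterogeneity);
* an optional total-oxidant coupling: a spatially uniform hourly Ox field is
  generated and O3 = Ox - NO2 (clipped at 0), so NO2 and O3 are
  anticorrelated in space while their sum is conserved — the titration
  mechanism that makes combined risk far smoother than either gas;
* PM fields intermediate between regional and local via a regional mass
  fraction;
* a heavily clustered population (Gaussian cluster mixture) and quadrant
  districts.

Everything is deterministic given the seed. Concentrations are generated
directly in ug/m3.

``brute_force_phni`` re-derives %AR, SF, network representativeness and PHNI
with plain nested Python loops sharing no code with the main pipeline; it is
the independent oracle for pipeline equivalence tests and is deliberately
restricted to small instances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .grid import (
    POLLUTANTS,
    ConcentrationField,
    GridSpec,
    PopulationRaster,
    StationRecord,
    locate_pseudo_stations,
)
from .health import DEFAULT_BETA, RiskCoefficients
from .representativeness import DomainMask, quadrant_districts

__all__ = [
    "SourceConfig",
    "BackgroundConfig",
    "PopulationConfig",
    "ScenarioConfig",
    "Scenario",
    "generate_scenario",
    "brute_force_phni",
    "BruteForceResult",
]


@dataclass(frozen=True)
class SourceConfig:
    """A localized emission source producing an exponential-decay plume.

    ``kind`` is "point" (coords = (x, y)) or "line" (coords = endpoint pair),
    ``strength`` the concentration the plume adds at zero distance (ug/m3)
    and ``decay_m`` the e-folding distance of the plume in metres.
    """

    kind: str
    coords: tuple
    strength: float
    decay_m: float

    def __post_init__(self) -> None:
        if self.kind not in ("point", "line"):
            raise ValueError(f"source kind must be 'point' or 'line', got {self.kind!r}")
        if not self.decay_m > 0:
            raise ValueError(f"decay_m must be positive, got {self.decay_m}")
        if self.strength < 0:
            raise ValueError(f"strength must be nonnegative, got {self.strength}")


@dataclass(frozen=True)
class BackgroundConfig:
    """Spatially constant AR(1) background: mean level, persistence, noise sd."""

    mean: float
    ar1: float = 0.7
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.ar1 < 1:
            raise ValueError(f"AR(1) coefficient must be in [0, 1), got {self.ar1}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be nonnegative, got {self.noise_sd}")
        if self.mean < 0:
            raise ValueError(f"background mean must be nonnegative, got {self.mean}")


@dataclass(frozen=True)
class PopulationConfig:
    """Gaussian-cluster mixture population model."""

    n_clusters: int = 4
    cluster_sd_m: float = 120.0
    total_persons: float = 100_000.0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("population needs at least one cluster")
        if not self.total_persons > 0:
            raise ValueError(f"total_persons must be positive, got {self.total_persons}")
        if not self.cluster_sd_m > 0:
            raise ValueError(f"cluster_sd_m must be positive, got {self.cluster_sd_m}")


def _default_backgrounds() -> dict[str, BackgroundConfig]:
    # Annual-mean-scale urban levels, ug/m3; PM persistence higher (regional
    # transport), gases more variable hour to hour.
    return {
        "PM10": BackgroundConfig(mean=35.0, ar1=0.85, noise_sd=4.0),
        "PM2.5": BackgroundConfig(mean=20.0, ar1=0.85, noise_sd=2.5),
        "NO2": BackgroundConfig(mean=25.0, ar1=0.7, noise_sd=4.0),
        "O3": BackgroundConfig(mean=70.0, ar1=0.7, noise_sd=8.0),
    }


@dataclass
class ScenarioConfig:
    """Everything needed to generate one scenario; seed is mandatory."""

    seed: int
    n_rows: int = 30
    n_cols: int = 30
    dx: float = 45.0
    dy: float = 48.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    n_hours: int = 720
    start: str = "2019-01-01"
    background: dict[str, BackgroundConfig] = dc_field(default_factory=_default_backgrounds)
    sources: dict[str, list[SourceConfig]] | None = None
    coupling: str = "ox_conserved"  # or "independent"
    ox_background: BackgroundConfig = dc_field(
        default_factory=lambda: BackgroundConfig(mean=180.0, ar1=0.8, noise_sd=8.0)
    )
    pm_regional_fraction: float = 0.65
    spatial_noise_sd: float = 0.0
    population: PopulationConfig = dc_field(default_factory=PopulationConfig)
    n_general: int = 3
    n_roadside: int = 1
    n_background: int = 1
    monthly_scale: dict[int, float] | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("an explicit seed is required")
        if self.coupling not in ("ox_conserved", "independent"):
            raise ValueError(f"coupling must be 'ox_conserved' or 'independent', got {self.coupling!r}")
        if not 0 <= self.pm_regional_fraction <= 1:
            raise ValueError(f"pm_regional_fraction must be in [0, 1], got {self.pm_regional_fraction}")
        if self.spatial_noise_sd < 0:
            raise ValueError(f"spatial_noise_sd must be nonnegative, got {self.spatial_noise_sd}")
        if self.n_hours < 1:
            raise ValueError(f"n_hours must be positive, got {self.n_hours}")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(
            origin_x=self.origin_x, origin_y=self.origin_y,
            n_cols=self.n_cols, n_rows=self.n_rows, dx=self.dx, dy=self.dy,
        )

    def default_sources(self) -> dict[str, list[SourceConfig]]:
        """Two crossing line sources ("roads"): NO2 plumes plus weaker PM plumes."""
        g = self.grid
        w, h = g.x_max - g.origin_x, g.y_max - g.origin_y
        road_h = SourceConfig(
            "line",
            ((g.origin_x, g.origin_y + 0.4 * h), (g.x_max, g.origin_y + 0.4 * h)),
            strength=50.0, decay_m=120.0,
        )
        road_v = SourceConfig(
            "line",
            ((g.origin_x + 0.65 * w, g.origin_y), (g.origin_x + 0.65 * w, g.y_max)),
            strength=40.0, decay_m=120.0,
        )
        pm_scale10 = (1 - self.pm_regional_fraction) * 35.0 / 50.0
        pm_scale25 = (1 - self.pm_regional_fraction) * 20.0 / 50.0
        return {
            "NO2": [road_h, road_v],
            "PM10": [SourceConfig("line", road_h.coords, road_h.strength * pm_scale10, 150.0)],
            "PM2.5": [SourceConfig("line", road_h.coords, road_h.strength * pm_scale25, 150.0)],
            "O3": [],
        }


@dataclass
class Scenario:
    """A generated scenario: inputs for the whole evaluation pipeline."""

    config: ScenarioConfig
    grid: GridSpec
    times: pd.DatetimeIndex
    fields: dict[str, ConcentrationField]
    stations: list[StationRecord]
    population: PopulationRaster
    districts: list[DomainMask]


def _plume_kernel(grid: GridSpec, sources: list[SourceConfig]) -> np.ndarray:
    """Static spatial kernel sum_s strength_s * exp(-dist/decay_s), (rows, cols)."""
    xs, ys = grid.center_mesh()
    kernel = np.zeros(grid.shape)
    for s in sources:
        if s.kind == "point":
            px, py = s.coords
            dist = np.hypot(xs - px, ys - py)
        else:
            (x1, y1), (x2, y2) = s.coords
            vx, vy = x2 - x1, y2 - y1
            seg2 = vx * vx + vy * vy
            if seg2 == 0:
                dist = np.hypot(xs - x1, ys - y1)
            else:
                t = np.clip(((xs - x1) * vx + (ys - y1) * vy) / seg2, 0.0, 1.0)
                dist = np.hypot(xs - (x1 + t * vx), ys - (y1 + t * vy))
        kernel += s.strength * np.exp(-dist / s.decay_m)
    return kernel


def _ar1_series(rng: np.random.Generator, n: int, cfg: BackgroundConfig) -> np.ndarray:
    """Stationary AR(1) deviations around cfg.mean, clipped at 0."""
    x = np.empty(n)
    sd0 = cfg.noise_sd / math.sqrt(1 - cfg.ar1**2) if cfg.noise_sd > 0 else 0.0
    x[0] = rng.normal(0.0, sd0) if sd0 > 0 else 0.0
    shocks = rng.normal(0.0, cfg.noise_sd, size=n - 1) if cfg.noise_sd > 0 else np.zeros(n - 1)
    for t in range(1, n):
        x[t] = cfg.ar1 * x[t - 1] + shocks[t - 1]
    return np.clip(cfg.mean + x, 0.0, None)


def _diurnal_modulation(times: pd.DatetimeIndex) -> np.ndarray:
    """Traffic-like diurnal factor in [0.6, 1.4], peaking in the morning."""
    hour = times.hour.to_numpy()
    return 1.0 + 0.4 * np.sin(2 * np.pi * (hour - 3.0) / 24.0)


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Build concentration fields, stations, population and districts.

    Fields are background + plume * diurnal modulation (+ optional iid
    spatial noise); in ``ox_conserved`` coupling O3 is derived as
    Ox - NO2 so their sum is spatially uniform each hour wherever O3 is not
    titrated to zero. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    times = pd.date_range(config.start, periods=config.n_hours, freq="h")
    sources = config.sources if config.sources is not None else config.default_sources()
    mod = _diurnal_modulation(times)

    month_scale = np.ones(len(times))
    if config.monthly_scale:
        month = times.month.to_numpy()
        for m, f in config.monthly_scale.items():
            month_scale[month == m] = f

    def build(pollutant: str, bg_series: np.ndarray) -> np.ndarray:
        kernel = _plume_kernel(grid, sources.get(pollutant, []))
        vals = bg_series[:, None, None] + kernel[None, :, :] * mod[:, None, None]
        if config.spatial_noise_sd > 0:
            vals = vals + rng.normal(0.0, config.spatial_noise_sd, size=vals.shape)
        return np.clip(vals, 0.0, None)

    fields: dict[str, ConcentrationField] = {}
    bg = {p: _ar1_series(rng, len(times), config.background[p]) * month_scale for p in POLLUTANTS}

    if config.coupling == "ox_conserved":
        ox = _ar1_series(rng, len(times), config.ox_background) * month_scale
        no2_vals = build("NO2", bg["NO2"])
        o3_vals = np.clip(ox[:, None, None] - no2_vals, 0.0, None)
        fields["NO2"] = ConcentrationField(grid, "NO2", "ug/m3", times, no2_vals)
        fields["O3"] = ConcentrationField(grid, "O3", "ug/m3", times, o3_vals)
    else:
        fields["NO2"] = ConcentrationField(grid, "NO2", "ug/m3", times, build("NO2", bg["NO2"]))
        fields["O3"] = ConcentrationField(grid, "O3", "ug/m3", times, build("O3", bg["O3"]))

    frac = config.pm_regional_fraction
    for p in ("PM10", "PM2.5"):
        # regional share is spatially flat; the plume term carries the local share
        regional = frac * bg[p] + (1 - frac) * bg[p].mean()
        fields[p] = ConcentrationField(grid, p, "ug/m3", times, build(p, regional))

    population, cluster_centers = _clustered_population(rng, grid, config.population)
    stations = _place_stations(rng, grid, config, sources, cluster_centers)
    districts = quadrant_districts(grid)
    return Scenario(
        config=config, grid=grid, times=times, fields=fields,
        stations=stations, population=population, districts=districts,
    )


def _clustered_population(
    rng: np.random.Generator, grid: GridSpec, cfg: PopulationConfig
) -> tuple[PopulationRaster, list[tuple[float, float]]]:
    xs, ys = grid.center_mesh()
    w, h = grid.x_max - grid.origin_x, grid.y_max - grid.origin_y
    centers = [
        (grid.origin_x + (0.15 + 0.7 * rng.random()) * w,
         grid.origin_y + (0.15 + 0.7 * rng.random()) * h)
        for _ in range(cfg.n_clusters)
    ]
    density = np.zeros(grid.shape)
    for cx, cy in centers:
        d2 = (xs - cx) ** 2 + (ys - cy) ** 2
        density += np.exp(-d2 / (2 * cfg.cluster_sd_m**2))
    total = density.sum()
    counts = density * (cfg.total_persons / total) if total > 0 else np.full(grid.shape, cfg.total_persons / grid.n_cells)
    return PopulationRaster(grid=grid, counts=counts), centers


def _place_stations(
    rng: np.random.Generator,
    grid: GridSpec,
    config: ScenarioConfig,
    sources: dict[str, list[SourceConfig]],
    cluster_centers: list[tuple[float, float]],
) -> list[StationRecord]:
    """General stations at population clusters, roadside on source lines,
    background at the corner farthest from every source."""
    records: list[StationRecord] = []
    for i in range(config.n_general):
        cx, cy = cluster_centers[i % len(cluster_centers)]
        jitter = (rng.uniform(-0.5, 0.5) * grid.dx, rng.uniform(-0.5, 0.5) * grid.dy) if i >= len(cluster_centers) else (0.0, 0.0)
        records.append(StationRecord(
            id=f"G{i + 1}", station_type="general",
            x=min(max(cx + jitter[0], grid.origin_x), grid.x_max - 1e-6),
            y=min(max(cy + jitter[1], grid.origin_y), grid.y_max - 1e-6),
            inlet_height=20.0,
        ))
    line_sources = [s for srcs in sources.values() for s in srcs if s.kind == "line"]
    for i in range(config.n_roadside):
        if line_sources:
            (x1, y1), (x2, y2) = line_sources[i % len(line_sources)].coords
            t = 0.3 + 0.4 * rng.random()
            x, y = x1 + t * (x2 - x1), y1 + t * (y2 - y1)
        else:
            x = grid.origin_x + rng.random() * (grid.x_max - grid.origin_x)
            y = grid.origin_y + rng.random() * (grid.y_max - grid.origin_y)
        records.append(StationRecord(
            id=f"R{i + 1}", station_type="roadside",
            x=min(max(x, grid.origin_x), grid.x_max - 1e-6),
            y=min(max(y, grid.origin_y), grid.y_max - 1e-6),
            inlet_height=4.0,
        ))
    if config.n_background:
        corners = [
            (grid.origin_x + 0.5 * grid.dx, grid.origin_y + 0.5 * grid.dy),
            (grid.x_max - 0.5 * grid.dx, grid.origin_y + 0.5 * grid.dy),
            (grid.origin_x + 0.5 * grid.dx, grid.y_max - 0.5 * grid.dy),
            (grid.x_max - 0.5 * grid.dx, grid.y_max - 0.5 * grid.dy),
        ]
        all_sources = [s for srcs in sources.values() for s in srcs]
        kernel_at = lambda x, y: sum(
            s.strength * math.exp(-_point_source_distance(s, x, y) / s.decay_m) for s in all_sources
        )
        corner = max(corners, key=lambda c: -kernel_at(*c)) if all_sources else corners[0]
        for i in range(config.n_background):
            records.append(StationRecord(
                id=f"B{i + 1}", station_type="background", x=corner[0], y=corner[1], inlet_height=11.0,
            ))
    return locate_pseudo_stations(records, grid)


def _point_source_distance(s: SourceConfig, x: float, y: float) -> float:
    if s.kind == "point":
        px, py = s.coords
        return math.hypot(x - px, y - py)
    (x1, y1), (x2, y2) = s.coords
    vx, vy = x2 - x1, y2 - y1
    seg2 = vx * vx + vy * vy
    if seg2 == 0:
        return math.hypot(x - x1, y - y1)
    t = min(max(((x - x1) * vx + (y - y1) * vy) / seg2, 0.0), 1.0)
    return math.hypot(x - (x1 + t * vx), y - (y1 + t * vy))


# ---------------------------------------------------------------------------
# Independent brute-force oracle


@dataclass
class BruteForceResult:
    """Loop-computed SF maps, network R maps and PHNI per pollutant/total."""

    sf: dict[str, dict[str, list[list[float | None]]]]  # field -> station -> [row][col]
    r: dict[str, list[list[float | None]]]
    phni: dict[str, float]


def brute_force_phni(
    scenario: Scenario,
    coeffs: RiskCoefficients | None = None,
    threshold: float = 0.2,
    cutoff: float = 0.9,
    min_coverage: float = 0.75,
    eps: float = 1e-9,
) -> BruteForceResult:
    """Re-derive %AR, SF, R and PHNI with plain nested loops.

    Shares no code with the vectorized pipeline (scalar ``math`` arithmetic
    throughout); restricted to grids of at most 50x50 cells and 2000 hours.
    The ``cutoff`` argument is accepted for interface symmetry with the
    pipeline's represented-area tallies but does not enter PHNI.
    """
    grid = scenario.grid
    if grid.n_rows > 50 or grid.n_cols > 50:
        raise ValueError("brute-force oracle is limited to grids of at most 50x50 cells")
    nt = len(scenario.times)
    if nt > 2000:
        raise ValueError("brute-force oracle is limited to at most 2000 hours")
    beta = dict((coeffs or RiskCoefficients()).beta)

    nr, nc = grid.n_rows, grid.n_cols
    # %AR per pollutant as [row][col][t] nested lists
    ar: dict[str, list] = {}
    for p in POLLUTANTS:
        vals = scenario.fields[p].values
        ar[p] = [
            [
                [
                    (math.expm1(beta[p] * vals[t, r, c]) * 100.0) if math.isfinite(vals[t, r, c]) else None
                    for t in range(nt)
                ]
                for c in range(nc)
            ]
            for r in range(nr)
        ]
    ar["total"] = [
        [
            [
                None
                if any(ar[p][r][c][t] is None for p in POLLUTANTS)
                else ar["NO2"][r][c][t] + ar["O3"][r][c][t] + max(ar["PM2.5"][r][c][t], ar["PM10"][r][c][t])
                for t in range(nt)
            ]
            for c in range(nc)
        ]
        for r in range(nr)
    ]

    sf_all: dict[str, dict[str, list]] = {}
    r_all: dict[str, list] = {}
    phni_all: dict[str, float] = {}
    pop = scenario.population.counts

    for name, cube in ar.items():
        sf_all[name] = {}
        for st in scenario.stations:
            r0, c0 = st.cell_index
            ref_series = cube[r0][c0]
            sf_grid: list[list[float | None]] = []
            for r in range(nr):
                row_vals: list[float | None] = []
                for c in range(nc):
                    series = cube[r][c]
                    n_valid = 0
                    n_similar = 0
                    for t in range(nt):
                        a, b = series[t], ref_series[t]
                        if a is None or b is None:
                            continue
                        n_valid += 1
                        if b < eps:
                            if abs(a - b) < eps:
                                n_similar += 1
                        elif abs(a - b) <= threshold * b:
                            n_similar += 1
                    if r == r0 and c == c0 and n_valid > 0:
                        row_vals.append(1.0)  # reflexivity regardless of coverage
                    elif n_valid == 0 or n_valid < min_coverage * nt:
                        row_vals.append(None)
                    else:
                        row_vals.append(n_similar / n_valid)
                sf_grid.append(row_vals)
            sf_all[name][st.id] = sf_grid

        r_grid: list[list[float | None]] = []
        for r in range(nr):
            row_vals = []
            for c in range(nc):
                best = None
                for st in scenario.stations:
                    v = sf_all[name][st.id][r][c]
                    if v is not None and (best is None or v > best):
                        best = v
                row_vals.append(best)
            r_grid.append(row_vals)
        r_all[name] = r_grid

        num = 0.0
        den = 0.0
        for r in range(nr):
            for c in range(nc):
                v = r_grid[r][c]
                if v is None:
                    continue
                num += v * pop[r, c]
                den += pop[r, c]
        phni_all[name] = num / den if den > 0 else float("nan")

    return BruteForceResult(sf=sf_all, r=r_all, phni=phni_all)
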