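"""End-to-end network evaluation: concentrations -> %AR -> SF -> R -> PHNI.

``evaluate_network`` runs the whole representativeness analysis for the four
pollutants and their combined risk, per period (annual and/or seasons),
returning SF maps, network representativeness maps, station-level
represented area/population summaries and global plus per-district PHNI
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import POLLUTANTS, ConcentrationField, PopulationRaster, StationRecord
from .health import ARField, ARTotalField, RiskCoefficients, compute_ar, compute_ar_total, convert_units
from .representativeness import (
    DomainMask,
    PHNIResult,
    RepresentativenessMap,
    StationSummary,
    network_representativeness,
    phni,
    represented_area,
    represented_population,
    seasonal_periods,
    district_phni,
)
from .similarity import SFMap, sf_map

__all__ = ["EvaluationResult", "evaluate_network"]

FIELD_NAMES = POLLUTANTS + ("total",)
PERIODS = ("annual", "spring", "summer", "autumn", "winter")


@dataclass
class EvaluationResult:
    """All evaluation outputs keyed by (field name, period)."""

    sf_maps: dict[tuple[str, str], list[SFMap]] = field(default_factory=dict)
    r_maps: dict[tuple[str, str], RepresentativenessMap] = field(default_factory=dict)
    station_summaries: list[StationSummary] = field(default_factory=list)
    phni_results: list[PHNIResult] = field(default_factory=list)

    def phni_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.pollutant, r.domain, r.period, r.phni, r.population_covered) for r in self.phni_results],
            columns=["pollutant", "domain", "period", "phni", "population"],
        )

    def station_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.station_id, s.pollutant, s.period, s.represented_area_km2, s.represented_population)
             for s in self.station_summaries],
            columns=["station_id", "pollutant", "period", "area_km2", "population"],
        )

    def phni_lookup(self, pollutant: str, period: str = "annual", domain: str = "all") -> float:
        for r in self.phni_results:
            if (r.pollutant, r.period, r.domain) == (pollutant, period, domain):
                return r.phni
        raise KeyError(f"no PHNI for ({pollutant}, {period}, {domain})")


def evaluate_network(
    fields: dict[str, ConcentrationField],
    stations: list[StationRecord],
    population: PopulationRaster,
    districts: list[DomainMask] | list | None = None,
    coeffs: RiskCoefficients | None = None,
    threshold: float = 0.2,
    cutoff: float = 0.9,
    min_coverage: float = 0.75,
    periods: tuple[str, ...] = ("annual",),
    field_names: tuple[str, ...] = FIELD_NAMES,
    reference: str = "station",
    temperature_C: float = 25.0,
    pressure_hPa: float = 1013.25,
) -> EvaluationResult:
    """Run the full representativeness evaluation.

    Parameters
    ----------
    fields
        One ``ConcentrationField`` per pollutant (all four are required when
        the combined risk is evaluated); ppb fields are converted to ug/m3.
    stations
        Located pseudo-stations (``cell_index`` set).
    districts
        Optional ``DomainMask`` list or (name, polygon) pairs for
        district-level PHNI; the whole-domain PHNI is always computed.
    periods
        Subset of ``("annual", "spring", "summer", "autumn", "winter")``.
    """
    missing = set(POLLUTANTS) - set(fields)
    if "total" in field_names and missing:
        raise ValueError(f"combined risk needs all four pollutants; missing {sorted(missing)}")
    if not stations:
        raise ValueError("no stations to evaluate")
    if any(s.cell_index is None for s in stations):
        raise ValueError("stations must be located on the grid first")
    coeffs = coeffs or RiskCoefficients()

    fields_ug = {p: convert_units(f, temperature_C, pressure_hPa) for p, f in fields.items()}
    ar: dict[str, ARField | ARTotalField] = {
        p: compute_ar(f, coeffs) for p, f in fields_ug.items()
    }
    if "total" in field_names:
        ar["total"] = compute_ar_total(ar["PM2.5"], ar["PM10"], ar["NO2"], ar["O3"])

    some_field = next(iter(ar.values()))
    masks = seasonal_periods(some_field.times)
    unknown = set(periods) - set(masks)
    if unknown:
        raise ValueError(f"unknown periods {sorted(unknown)}")

    result = EvaluationResult()
    for name in field_names:
        fld = ar[name]
        for period in periods:
            pmask = masks[period]
            maps = []
            for st in stations:
                m = sf_map(
                    fld, st, period_mask=pmask, threshold=threshold,
                    min_coverage=min_coverage, reference=reference,
                )
                m.period = period
                maps.append(m)
                result.station_summaries.append(StationSummary(
                    station_id=st.id, pollutant=name, period=period,
                    represented_area_km2=represented_area(m, cutoff),
                    represented_population=represented_population(m, population, cutoff),
                ))
            result.sf_maps[(name, period)] = maps
            rmap = network_representativeness(maps)
            result.r_maps[(name, period)] = rmap
            result.phni_results.append(phni(rmap, population))
            if districts:
                result.phni_results.extend(district_phni(rmap, population, districts))
    return result
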