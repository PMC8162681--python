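"""Excess hospital-admission risk (%AR) from pollutant concentrations.

Short-term excess risk follows the additive air-quality-health-index form:
``%AR = (exp(beta * C) - 1) * 100`` with ``C`` in ug/m3 and ``beta`` the
pollutant-specific admission-rate slope per ug/m3. The combined risk at a
cell/hour sums the NO2 and O3 terms with the larger of the two PM size
fractions, so risks of different pollutants become comparable and additive.

Default slopes are the Hong Kong all-ages hospital-admission coefficients
(Wong et al.); they yield 0.51% per 10 ug/m3 of O3 and 0.28% per 10 ug/m3 of
PM10. Gaseous concentrations reported in ppb are converted to ug/m3 with the
ideal-gas molar volume at configurable temperature and pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import ConcentrationField, GridSpec

__all__ = [
    "RiskCoefficients",
    "ARField",
    "ARTotalField",
    "convert_units",
    "compute_ar",
    "compute_ar_total",
]

#: Wong et al. all-ages hospital-admission excess-risk slopes, per ug/m3.
DEFAULT_BETA = {
    "PM2.5": 2.180567e-4,
    "PM10": 2.821751e-4,
    "NO2": 4.462559e-4,
    "O3": 5.116328e-4,
}

MOLAR_MASS_G_MOL = {"NO2": 46.0055, "O3": 48.00}

#: Conventional molar volume at 25 degC / 1013.25 hPa used in AQ reporting.
MOLAR_VOLUME_REF_L = 24.45
TEMP_REF_C = 25.0
PRESSURE_REF_HPA = 1013.25


@dataclass(frozen=True)
class RiskCoefficients:
    """Excess-risk slopes beta (per ug/m3) per pollutant, with provenance."""

    beta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    provenance: str = "Wong et al. Hong Kong AQHI all-ages hospital-admission coefficients"

    def __post_init__(self) -> None:
        for p, b in self.beta.items():
            if not (b > 0):
                raise ValueError(f"beta must be positive; got {b} for {p}")

    def __getitem__(self, pollutant: str) -> float:
        try:
            return self.beta[pollutant]
        except KeyError:
            raise KeyError(f"no risk coefficient for pollutant {pollutant!r}") from None


@dataclass
class ARField:
    """Hourly excess risk %AR for one pollutant on the grid (percent)."""

    grid: GridSpec
    pollutant: str
    times: pd.DatetimeIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.times), self.grid.n_rows, self.grid.n_cols)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def series_at(self, row: int, col: int) -> np.ndarray:
        return self.values[:, row, col]


@dataclass
class ARTotalField:
    """Hourly combined excess risk %AR_total on the grid (percent)."""

    grid: GridSpec
    times: pd.DatetimeIndex
    values: np.ndarray
    pollutant: str = "total"

    __post_init__ = ARField.__post_init__
    mask = ARField.mask
    series_at = ARField.series_at


def molar_volume_l(temperature_C: float = TEMP_REF_C, pressure_hPa: float = PRESSURE_REF_HPA) -> float:
    """Ideal-gas molar volume (L/mol), anchored at 24.45 L/mol for 25 degC, 1013.25 hPa."""
    t_k = temperature_C + 273.15
    return MOLAR_VOLUME_REF_L * (t_k / (TEMP_REF_C + 273.15)) * (PRESSURE_REF_HPA / pressure_hPa)


def convert_units(
    fld: ConcentrationField,
    temperature_C: float = TEMP_REF_C,
    pressure_hPa: float = PRESSURE_REF_HPA,
) -> ConcentrationField:
    """Convert a gaseous field from ppb to ug/m3; ug/m3 fields pass through.

    ug/m3 = ppb * M / V_m with M the molar mass and V_m the molar volume at
    the given conditions (24.45 L/mol at the 25 degC / 1013.25 hPa default).
    """
    if fld.unit in ("ug/m3", "µg/m³"):
        return fld
    if fld.unit != "ppb":
        raise ValueError(f"unsupported unit {fld.unit!r}")
    if fld.pollutant not in MOLAR_MASS_G_MOL:
        raise ValueError(f"ppb unit is only meaningful for gaseous pollutants, not {fld.pollutant}")
    factor = MOLAR_MASS_G_MOL[fld.pollutant] / molar_volume_l(temperature_C, pressure_hPa)
    return ConcentrationField(
        grid=fld.grid, pollutant=fld.pollutant, unit="ug/m3",
        times=fld.times, values=fld.values * factor,
    )


def compute_ar(fld: ConcentrationField, coeffs: RiskCoefficients | None = None) -> ARField:
    """Elementwise %AR = (exp(beta * C) - 1) * 100; missing values propagate."""
    if fld.unit not in ("ug/m3", "µg/m³"):
        raise ValueError(f"concentrations must be in ug/m3, got {fld.unit!r}; convert first")
    coeffs = coeffs or RiskCoefficients()
    beta = coeffs[fld.pollutant]
    values = np.expm1(beta * fld.values) * 100.0
    return ARField(grid=fld.grid, pollutant=fld.pollutant, times=fld.times, values=values)


def excess_risk_percent(concentration_ug_m3, pollutant: str, coeffs: RiskCoefficients | None = None):
    """Scalar/array convenience form of the %AR transform."""
    coeffs = coeffs or RiskCoefficients()
    return np.expm1(coeffs[pollutant] * np.asarray(concentration_ug_m3, dtype=float)) * 100.0


def compute_ar_total(
    ar_pm25: ARField, ar_pm10: ARField, ar_no2: ARField, ar_o3: ARField
) -> ARTotalField:
    """Combined risk: NO2 + O3 + max(PM2.5, PM10), per cell and hour.

    The PM term takes whichever size fraction carries the higher risk at each
    cell/hour (the fractions overlap physically, so they are not summed).
    Missing values in any input make the combined value missing.
    """
    fields = {"PM2.5": ar_pm25, "PM10": ar_pm10, "NO2": ar_no2, "O3": ar_o3}
    ref = ar_no2
    for name, f in fields.items():
        if f.pollutant != name:
            raise ValueError(f"expected {name} field, got {f.pollutant}")
        if f.grid != ref.grid:
            raise ValueError(f"grid mismatch between NO2 and {name} fields")
        if not f.times.equals(ref.times):
            raise ValueError(f"time-axis mismatch between NO2 and {name} fields")
    values = ar_no2.values + ar_o3.values + np.maximum(ar_pm25.values, ar_pm10.values)
    return ARTotalField(grid=ref.grid, times=ref.times, values=values)
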