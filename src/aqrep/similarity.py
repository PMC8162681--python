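"""Similarity frequency (SF) between grid-cell and pseudo-station risk series.

SF is the fraction of timesteps at which two series agree to within a
relative threshold (default 20%). Computed between every cell's %AR series
and a pseudo-station's %AR series it yields a per-station representativeness
map in [0, 1]; SF > 0.9 marks a well-represented cell.

The station series is the reference (denominator) of the relative
difference: the station is the object whose representativeness is being
evaluated. A symmetric variant (denominator = the larger of the pair) is
available via ``reference="max"``. Timesteps missing in either series are
excluded; below a minimum coverage fraction the SF is undefined (NaN).
Near-zero reference values are compared absolutely against a small epsilon
to avoid division blow-up (%AR is exactly zero at zero concentration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GridSpec, StationRecord

__all__ = ["SFMap", "similarity_frequency", "sf_map", "classify_band", "BANDS"]

#: Band edges: low [0, 0.5), medium [0.5, 0.7), medium_high [0.7, 0.9], high (0.9, 1].
BANDS = ("low", "medium", "medium_high", "high")

WELL_REPRESENTED_CUTOFF = 0.9


@dataclass
class SFMap:
    """Per-cell similarity frequency against one pseudo-station.

    ``values`` in [0, 1] or NaN where undefined; ``n_valid`` counts the
    timesteps actually compared per cell.
    """

    grid: GridSpec
    station_id: str
    values: np.ndarray
    n_valid: np.ndarray
    pollutant: str = ""
    period: str = "annual"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.n_valid = np.asarray(self.n_valid, dtype=int)
        if self.values.shape != self.grid.shape or self.n_valid.shape != self.grid.shape:
            raise ValueError("SF map arrays must match the grid shape")
        with np.errstate(invalid="ignore"):
            if np.any((self.values < 0) | (self.values > 1)):
                raise ValueError("SF values must lie in [0, 1]")


def _validate_sf_params(threshold: float, min_coverage: float, reference: str) -> None:
    if not threshold > 0:
        raise ValueError(f"similarity threshold must be positive, got {threshold}")
    if not 0 <= min_coverage <= 1:
        raise ValueError(f"min_coverage must be in [0, 1], got {min_coverage}")
    if reference not in ("station", "max"):
        raise ValueError(f"reference must be 'station' or 'max', got {reference!r}")


def similarity_frequency(
    cell_series,
    station_series,
    threshold: float = 0.2,
    min_coverage: float = 0.75,
    eps: float = 1e-9,
    reference: str = "station",
) -> tuple[float, int]:
    """SF between one cell series and one station (reference) series.

    Returns ``(sf, n_valid)``; ``sf`` is NaN when fewer than
    ``min_coverage * len(series)`` timesteps are present in both series.
    """
    _validate_sf_params(threshold, min_coverage, reference)
    a = np.asarray(cell_series, dtype=float)
    b = np.asarray(station_series, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and share a time axis")
    valid = np.isfinite(a) & np.isfinite(b)
    n_valid = int(valid.sum())
    if n_valid < min_coverage * a.size or n_valid == 0:
        return float("nan"), n_valid
    av, bv = a[valid], b[valid]
    ref = np.maximum(av, bv) if reference == "max" else bv
    degenerate = ref < eps
    with np.errstate(divide="ignore", invalid="ignore"):
        similar = np.where(degenerate, np.abs(av - bv) < eps, np.abs(av - bv) <= threshold * ref)
    return float(similar.sum() / n_valid), n_valid


def sf_map(
    ar_field,
    station: StationRecord,
    period_mask=None,
    threshold: float = 0.2,
    min_coverage: float = 0.75,
    eps: float = 1e-9,
    reference: str = "station",
) -> SFMap:
    """SF of every cell against one pseudo-station, over selected timesteps.

    ``ar_field`` is an ``ARField`` or ``ARTotalField``; ``period_mask`` is a
    boolean selector on its time axis (annual when None). The station's own
    cell is 1 by reflexivity. Raises if the station's series is entirely
    missing over the period.
    """
    _validate_sf_params(threshold, min_coverage, reference)
    if station.cell_index is None:
        raise ValueError(f"station {station.id} has not been located on the grid")
    vals = ar_field.values
    if period_mask is not None:
        period_mask = np.asarray(period_mask, dtype=bool)
        if period_mask.shape != (vals.shape[0],):
            raise ValueError("period_mask must match the field's time axis")
        vals = vals[period_mask]
    r0, c0 = station.cell_index
    b = vals[:, r0, c0]  # (T,)
    if not np.isfinite(b).any():
        raise ValueError(f"station {station.id} cell is fully missing over the period")

    nt = vals.shape[0]
    finite_a = np.isfinite(vals)
    finite_b = np.isfinite(b)[:, None, None]
    valid = finite_a & finite_b
    n_valid = valid.sum(axis=0)

    b3 = b[:, None, None]
    if reference == "max":
        ref = np.where(valid, np.fmax(vals, b3), np.nan)
    else:
        ref = np.broadcast_to(b3, vals.shape)
    with np.errstate(invalid="ignore"):
        diff = np.abs(vals - b3)
        similar = np.where(ref < eps, diff < eps, diff <= threshold * ref)
    similar &= valid

    with np.errstate(invalid="ignore", divide="ignore"):
        sf = similar.sum(axis=0) / n_valid
    sf[n_valid < min_coverage * nt] = np.nan
    sf[n_valid == 0] = np.nan
    if n_valid[r0, c0] > 0:
        sf[r0, c0] = 1.0  # reflexivity, regardless of coverage
    return SFMap(
        grid=ar_field.grid, station_id=station.id, values=sf, n_valid=n_valid,
        pollutant=getattr(ar_field, "pollutant", ""),
    )


def classify_band(sf: float) -> str:
    """Band label for an SF value: low / medium / medium_high / high.

    ``high`` requires SF strictly greater than 0.9; 0.9 itself is
    ``medium_high``.
    """
    if not np.isfinite(sf) or sf < 0 or sf > 1:
        raise ValueError(f"SF must lie in [0, 1], got {sf}")
    if sf < 0.5:
        return "low"
    if sf < 0.7:
        return "medium"
    if sf <= 0.9:
        return "medium_high"
    return "high"
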