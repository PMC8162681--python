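"""Model-vs-observation agreement statistics: index of agreement and RMSE."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PairedSeries", "ioa", "rmse"]


@dataclass
class PairedSeries:
    """Predicted and observed hourly values on a shared time axis.

    Timesteps missing (NaN) in either series are dropped pairwise on
    construction; at least two valid pairs must remain.
    """

    predicted: np.ndarray
    observed: np.ndarray
    pollutant: str = ""
    station_id: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.predicted, dtype=float)
        o = np.asarray(self.observed, dtype=float)
        if p.shape != o.shape or p.ndim != 1:
            raise ValueError("predicted and observed must be 1-D and share a time axis")
        valid = np.isfinite(p) & np.isfinite(o)
        self.predicted = p[valid]
        self.observed = o[valid]
        if self.predicted.size < 2:
            raise ValueError("need at least 2 valid predicted/observed pairs")

    @property
    def n(self) -> int:
        return self.predicted.size


def ioa(pair: PairedSeries, printed_variant: bool = False) -> float:
    """Willmott index of agreement, in [0, 1]; 1 iff predicted == observed.

    IOA = 1 - sum (P_i - O_i)^2 / sum (|P_i - Obar| + |O_i - Obar|)^2.

    ``printed_variant=True`` switches the first denominator term to
    |P_i + Obar| (an occasionally printed but unbounded variant, kept for
    audit only). Returns NaN when the observations have zero variance, since
    the denominator then cannot normalize.
    """
    p, o = pair.predicted, pair.observed
    obar = o.mean()
    if np.ptp(o) == 0:
        return float("nan")
    num = np.sum((p - o) ** 2)
    first = np.abs(p + obar) if printed_variant else np.abs(p - obar)
    den = np.sum((first + np.abs(o - obar)) ** 2)
    return float(1.0 - num / den)


def rmse(pair: PairedSeries) -> float:
    """Root mean square error over the valid pairs."""
    return float(np.sqrt(np.mean((pair.predicted - pair.observed) ** 2)))
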