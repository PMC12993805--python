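"""Concentration→influx conversion and the proportional-relative-scaling
(PRS) transform.

PRS maps a whole charcoal-influx record onto a common 0–100 scale while
down-weighting records dominated by zero samples::

    Char_PRS,i = (C_i / C_max) * 100 * (f / N)

where C_i is a sample's influx, C_max the record maximum, f the number of
positive samples and N the record length. The transform is scale-invariant
(multiplying all influxes by k > 0 changes nothing) and suited to ecosystems
with infrequent fires where charcoal is sparsely recorded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .age_depth import AgeModelEnsemble, accumulation_rate
from .record_io import CONCENTRATION, INFLUX, CharcoalSeries

__all__ = [
    "InfluxSeries",
    "PRSSeries",
    "concentration_to_influx",
    "prs_transform",
    "median_prs",
    "cube_root",
]

logger = logging.getLogger(__name__)


@dataclass
class InfluxSeries:
    """Dated charcoal influx (particles cm^-2 yr^-1) for one site."""

    site_id: str
    age_ce: np.ndarray
    influx: np.ndarray
    n_dropped: int = 0  # samples outside the modelled depth range

    def __post_init__(self) -> None:
        self.age_ce = np.asarray(self.age_ce, dtype=float)
        self.influx = np.asarray(self.influx, dtype=float)
        if np.any(self.influx < 0):
            raise ValueError(f"{self.site_id}: negative influx")

    def __len__(self) -> int:
        return len(self.influx)


@dataclass
class PRSSeries:
    """PRS-transformed influx on the 0–100 scale for one site."""

    site_id: str
    age_ce: np.ndarray
    prs: np.ndarray
    f: int
    n: int
    c_max: float

    def __len__(self) -> int:
        return len(self.prs)


def concentration_to_influx(
    series: CharcoalSeries, model: AgeModelEnsemble
) -> InfluxSeries:
    """Convert a concentration series to influx via the site's age model.

    influx_i = concentration_i × accumulation_rate(midpoint depth_i), with the
    sample dated by the median chronology at its midpoint. Samples outside the
    modelled depth range are dropped (counted in ``n_dropped``). A series
    already in influx units passes through unchanged apart from dating.
    """
    mid = series.midpoints
    in_range = model.in_range(mid)
    n_dropped = int(np.sum(~in_range))
    if n_dropped:
        logger.info(
            "%s: dropped %d samples outside the modelled depth range",
            series.site_id,
            n_dropped,
        )
    if not np.any(in_range):
        raise ValueError(
            f"{series.site_id}: no overlap between sample depths and age model"
        )
    mid = mid[in_range]
    value = series.value[in_range]
    ages = model.age_at(mid)
    if series.unit == INFLUX:
        influx = value
    elif series.unit == CONCENTRATION:
        influx = value * accumulation_rate(model, mid)
    else:  # pragma: no cover - guarded by CharcoalSeries
        raise ValueError(f"unknown unit {series.unit!r}")
    return InfluxSeries(
        site_id=series.site_id, age_ce=ages, influx=influx, n_dropped=n_dropped
    )


def prs_transform(series: InfluxSeries) -> PRSSeries:
    """Apply proportional relative scaling to a whole influx record.

    f and N are computed over the full record (before any windowing or
    binning). An all-zero record maps to all zeros with c_max recorded as 0.
    """
    n = len(series)
    if n < 1:
        raise ValueError(f"{series.site_id}: empty influx record")
    f = int(np.sum(series.influx > 0))
    if f == 0:
        return PRSSeries(
            site_id=series.site_id,
            age_ce=series.age_ce.copy(),
            prs=np.zeros(n),
            f=0,
            n=n,
            c_max=0.0,
        )
    c_max = float(np.max(series.influx))
    prs = (series.influx / c_max) * 100.0 * (f / n)
    return PRSSeries(
        site_id=series.site_id,
        age_ce=series.age_ce.copy(),
        prs=prs,
        f=f,
        n=n,
        c_max=c_max,
    )


def median_prs(
    series: PRSSeries, window: tuple[float, float] = (0.0, 2000.0)
) -> float:
    """Median PRS over samples with age in [start, end]; NaN (with a warning)
    when the window is empty."""
    start, end = window
    sel = (series.age_ce >= start) & (series.age_ce <= end)
    if not np.any(sel):
        warnings.warn(
            f"{series.site_id}: no samples in window [{start}, {end}] CE",
            stacklevel=2,
        )
        return float("nan")
    return float(np.median(series.prs[sel]))


def cube_root(value: float) -> float:
    """Cube root, used to bring skewed median-PRS values toward normality."""
    if value < 0:
        raise ValueError("cube_root is defined for values >= 0 here")
    return float(np.cbrt(value))
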