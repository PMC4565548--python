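"""Rainfall phenology: moult windows, seasonality and amount-weighted δ²H.

For a sedentary tropical passerine, feather growth is assumed to follow
breeding, which tracks the rains.  From the 12 monthly precipitation
values at a locality we derive:

* the **peak month** — the calendar month with maximal rainfall;
* the **moult month** — two months after the peak (circular);
* the **moult season** — the four months after the peak (circular);
* the **Walsh–Lawler relative seasonality index**
  ``SI = (1/R) * Σ |x_n − R/12|`` where ``R`` is annual rainfall,
  ranging from 0 (perfectly even) to 22/12 ≈ 1.833 (all rain in one
  month); SI < 0.19 means rainfall spread through the year, SI > 1.2
  extreme seasonality;
* **amount-weighted precipitation δ²H** over a month window —
  ``Σ p_m δ_m / Σ p_m``.

Months are indexed 1–12 with circular arithmetic.  Array-valued inputs
are supported with months on a chosen axis, so the same code serves
per-sample vectors and per-pixel grid stacks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MoultWindow",
    "NoSeasonError",
    "WeightingError",
    "peak_month",
    "moult_window",
    "seasonality_index",
    "classify_seasonality",
    "amount_weighted_d2h",
    "SI_SPREAD_THRESHOLD",
    "SI_EXTREME_THRESHOLD",
    "SI_MAX",
]

SI_SPREAD_THRESHOLD = 0.19  # below: precipitation spread throughout the year
SI_EXTREME_THRESHOLD = 1.2  # above: extreme seasonality (rain in 1-2 months)
SI_MAX = 22.0 / 12.0  # attained when all rain falls in a single month

MOULT_MONTH_LAG = 2  # months after the rain peak
MOULT_SEASON_LENGTH = 4  # months, starting the month after the peak


class NoSeasonError(ValueError):
    """Raised for an all-zero rainfall year, where no season is defined."""


class WeightingError(ValueError):
    """Raised when a weighting window receives zero total rainfall."""


def _wrap_month(m: int) -> int:
    """Map any integer onto calendar months 1..12."""
    return (m - 1) % 12 + 1


@dataclass(frozen=True)
class MoultWindow:
    """Moult timing derived from the rainfall peak.

    ``month`` is the single most likely moult month (peak + 2);
    ``season`` is the four consecutive months after the peak, of which
    the moult month is the second.
    """

    month: int
    season: tuple[int, int, int, int]


def _validate_monthly(x, name: str = "monthly vector") -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.shape[-1] != 12:
        raise ValueError(f"{name} must have 12 entries on the last axis, got {arr.shape}")
    return arr


def peak_month(precip) -> int:
    """Month (1-12) of maximal rainfall; ties go to the earliest month."""
    arr = _validate_monthly(np.atleast_1d(np.asarray(precip, dtype=float)))
    if arr.ndim != 1:
        raise ValueError("peak_month operates on a single 12-month vector")
    if np.any(arr < 0):
        raise ValueError("precipitation must be non-negative")
    if not np.any(arr > 0):
        raise NoSeasonError("all-zero rainfall: no peak month defined")
    return int(np.argmax(arr)) + 1  # argmax returns the first maximum


def moult_window(precip) -> MoultWindow:
    """Moult month = peak + 2; moult season = peak+1 .. peak+4 (circular)."""
    peak = peak_month(precip)
    season = tuple(_wrap_month(peak + k) for k in range(1, MOULT_SEASON_LENGTH + 1))
    return MoultWindow(month=_wrap_month(peak + MOULT_MONTH_LAG), season=season)


def seasonality_index(precip, axis: int = -1):
    """Walsh–Lawler relative seasonality: (1/R)·Σ|x_n − R/12|.

    Accepts a 12-vector or an array with 12 months along ``axis``
    (e.g. a (12, nrows, ncols) grid stack with ``axis=0``).  Returns a
    scalar for vector input, an array otherwise; pixels with zero
    annual rainfall raise for vector input and yield NaN for arrays.
    """
    arr = np.asarray(precip, dtype=float)
    arr = np.moveaxis(arr, axis, -1)
    _validate_monthly(arr, "precipitation")
    if np.any(arr < 0):
        raise ValueError("precipitation must be non-negative")
    total = arr.sum(axis=-1)
    if arr.ndim == 1:
        if total == 0:
            raise NoSeasonError("zero annual rainfall: SI undefined")
        return float(np.abs(arr - total / 12.0).sum() / total)
    with np.errstate(invalid="ignore", divide="ignore"):
        si = np.abs(arr - total[..., None] / 12.0).sum(axis=-1) / total
    return np.where(total > 0, si, np.nan)


def classify_seasonality(si: float) -> str:
    """Qualitative regime label for a Walsh–Lawler index value."""
    if si < SI_SPREAD_THRESHOLD:
        return "spread"
    if si > SI_EXTREME_THRESHOLD:
        return "extreme"
    return "seasonal"


def amount_weighted_d2h(precip, d2h, months=None) -> float:
    """Precipitation-amount-weighted mean δ²H over a month window.

    ``months`` is an iterable of calendar months (1-12); ``None`` means
    the annual (all-12-months) variant.  Raises
    :class:`WeightingError` when the window holds no rain, rather than
    silently returning 0.
    """
    p = _validate_monthly(np.asarray(precip, dtype=float), "precipitation")
    d = _validate_monthly(np.asarray(d2h, dtype=float), "δ²H")
    if p.ndim != 1 or d.ndim != 1:
        raise ValueError("amount_weighted_d2h operates on single 12-month vectors")
    idx = np.arange(12) if months is None else np.array([_wrap_month(m) - 1 for m in months])
    w = p[idx]
    total = w.sum()
    if total <= 0:
        raise WeightingError("zero rainfall in the selected window: weighted δ²H undefined")
    return float((w * d[idx]).sum() / total)
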