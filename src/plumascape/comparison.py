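"""Isoscape comparison: aggregation, per-pixel mismatch and regression.

Two isoscapes built from different source data rarely share a lattice;
the finer raster is aggregated (block mean over source cells whose
centers fall in each coarse cell) onto the coarser one, the per-pixel
standard deviation of the two values maps the spatial distribution of
mismatch, and observed feather values are regressed on either
surface's predictions to quantify agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .grids import Grid

__all__ = ["ComparisonError", "RegressionReport", "resample", "sd_map", "regress_observed"]


class ComparisonError(ValueError):
    pass


def resample(grid: Grid, target_cell: float, method: str = "mean") -> Grid:
    """Aggregate a raster onto a coarser lattice of ``target_cell`` degrees.

    ``mean`` assigns every source cell (by its center) to the target
    cell containing it and averages the unmasked members; a target cell
    whose members are all nodata stays nodata.  ``nearest`` picks the
    source cell nearest each target-cell center.  Upsampling under
    ``mean`` is refused — block means are undefined in that direction.
    """
    if method not in ("mean", "nearest"):
        raise ComparisonError(f"unknown resampling method {method!r}")
    if method == "mean" and target_cell < grid.cell:
        raise ComparisonError(
            f"cannot block-average from {grid.cell}° up to finer {target_cell}°"
        )
    ncols_t = int(np.ceil((grid.east - grid.west) / target_cell - 1e-9))
    nrows_t = int(np.ceil((grid.north - grid.south) / target_cell - 1e-9))
    if method == "nearest":
        out = np.full((nrows_t, ncols_t), np.nan)
        for r in range(nrows_t):
            lat = grid.north - (r + 0.5) * target_cell
            for c in range(ncols_t):
                lon = grid.west + (c + 0.5) * target_cell
                try:
                    out[r, c] = grid.extract_at(lon, lat)
                except ValueError:
                    pass
        return Grid(out, grid.west, grid.north, target_cell)
    # block mean by binning source-cell centers into target cells
    src_lon = grid.lon_centers()
    src_lat = grid.lat_centers()
    cols_t = np.clip(((src_lon - grid.west) / target_cell).astype(int), 0, ncols_t - 1)
    rows_t = np.clip(((grid.north - src_lat) / target_cell).astype(int), 0, nrows_t - 1)
    sums = np.zeros((nrows_t, ncols_t))
    counts = np.zeros((nrows_t, ncols_t))
    valid = ~np.isnan(grid.data)
    rr, cc = np.meshgrid(rows_t, cols_t, indexing="ij")
    np.add.at(sums, (rr[valid], cc[valid]), grid.data[valid])
    np.add.at(counts, (rr[valid], cc[valid]), 1.0)
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return Grid(out, grid.west, grid.north, target_cell)


def sd_map(a: Grid, b: Grid, population: bool = False) -> Grid:
    """Per-pixel standard deviation of the two rasters' values.

    Sample (n−1) convention by default: SD = |a − b|/√2; the population
    version |a − b|/2 via ``population=True``.  Either input masked →
    output masked.  Requires co-registered lattices.
    """
    if not a.same_lattice(b):
        raise ComparisonError("sd_map requires co-registered rasters")
    denom = 2.0 if population else np.sqrt(2.0)
    return a.copy_with(np.abs(a.data - b.data) / denom)


@dataclass
class RegressionReport:
    """Simple regression of observed feather δ²H on isoscape predictions."""

    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    f_df: tuple[int, int]
    p_value: float
    n: int
    predicted: np.ndarray
    observed: np.ndarray


def regress_observed(
    samples: pd.DataFrame, raster: Grid, response: str = "d2h"
) -> RegressionReport:
    """OLS of observed values on raster predictions at sample points.

    Samples whose nearest cell is nodata (or outside the extent) are
    dropped; at least 3 must remain.  F is reported on (1, n−2) df.
    """
    obs, pred = [], []
    for rec in samples.to_dict("records"):
        try:
            value = raster.extract_at(float(rec["lon"]), float(rec["lat"]))
        except ValueError:
            continue
        if np.isnan(value) or pd.isna(rec[response]):
            continue
        obs.append(float(rec[response]))
        pred.append(value)
    if len(obs) < 3:
        raise ComparisonError(
            f"only {len(obs)} samples overlap the raster; need at least 3"
        )
    y = np.asarray(obs)
    x = np.asarray(pred)
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    return RegressionReport(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        f_statistic=float(res.fvalue),
        f_df=(int(res.df_model), int(res.df_resid)),
        p_value=float(res.f_pvalue),
        n=len(obs),
        predicted=x,
        observed=y,
    )
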