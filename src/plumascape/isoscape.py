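"""Pixel-wise application of the selected model: the predicted isoscape.

The selected OLS model is evaluated at every grid cell:

    δ²H(px) = β₀ + Σⱼ βⱼ·xⱼ(px) + Σ_{r≥2} w_r(px)·β_r

where the region offsets are blended by the fuzzy membership weights
(the baseline region contributes zero).  The output is the fixed-
effects surface only — no back-transform, no residual kriging.

The absolute-latitude covariate is derived from the lattice itself;
SI comes from the monthly precipitation stack (single source of truth
with the phenology stage).  All input grids must share one lattice —
a mismatch is an error, never a silent resample.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .grids import Grid, GridStack
from .modeling import ModelFit
from .phenology import seasonality_index

__all__ = [
    "IsoscapeError",
    "IsoscapeRaster",
    "predict_pixel",
    "predict_surface",
    "predict_raster",
    "summarize",
]


class IsoscapeError(ValueError):
    pass


@dataclass
class IsoscapeRaster:
    """Predicted feather-δ²H surface with provenance."""

    grid: Grid  # ‰ VSMOW; NaN where any input was nodata
    provenance: dict = dataclass_field(default_factory=dict)

    @property
    def mask(self) -> np.ndarray:
        return np.isnan(self.grid.data)


def predict_pixel(
    coeffs: dict[str, float], covariates: dict[str, float], weights
) -> float:
    """Evaluate the linear model at one pixel.

    ``coeffs`` maps term names (const, ABS_LAT, ABS_LAT2, ALT,
    PREC_TOT, SI, w_2..w_R) to estimates; terms absent from ``coeffs``
    simply do not contribute.  ``weights`` is the full membership
    vector w_1..w_R on the simplex; the baseline w_1 has no
    coefficient.  Any NaN input yields NaN (a masked cell).
    """
    weights = np.asarray(weights, dtype=float)
    if weights.size and not np.isclose(weights.sum(), 1.0, atol=1e-6):
        raise IsoscapeError(f"region weights must sum to 1, got {weights.sum()}")
    out = coeffs.get("const", 0.0)
    for name, beta in coeffs.items():
        if name == "const":
            continue
        if name.startswith("w_"):
            out += beta * weights[int(name[2:]) - 1]
        elif name == "ABS_LAT2":
            out += beta * covariates["ABS_LAT"] ** 2
        else:
            out += beta * covariates[name]
    return float(out)


def _check_registration(named_grids: dict[str, Grid]) -> None:
    ref_name, ref = next(iter(named_grids.items()))
    bad = [name for name, g in named_grids.items() if not ref.same_lattice(g)]
    if bad:
        raise IsoscapeError(
            f"grids not co-registered with {ref_name!r}: {', '.join(bad)}"
        )


def predict_surface(
    coeffs,
    altitude: Grid,
    climate: GridStack,
    membership: GridStack,
) -> Grid:
    """Evaluate a coefficient mapping over co-registered covariate grids.

    ``coeffs`` is any mapping from term names to estimates (a fitted
    model's parameter series, or a known generating model).  PREC_TOT
    and SI are derived per pixel from the monthly stack; ABS_LAT from
    the cell-center latitudes.  The output mask is the union of input
    nodata masks.
    """
    _check_registration(
        {
            "altitude": altitude,
            "climate": climate.grid,
            "membership": membership.grid,
        }
    )
    months = climate.as_array()
    prec_tot = months.sum(axis=0)
    si = seasonality_index(months, axis=0)
    lat = altitude.lat_centers()[:, None] * np.ones_like(altitude.data)
    abs_lat = np.abs(lat)
    memb = membership.as_array()

    surface = np.full_like(altitude.data, coeffs.get("const", 0.0))
    term_grids = {
        "ABS_LAT": abs_lat,
        "ABS_LAT2": abs_lat**2,
        "ALT": altitude.data,
        "PREC_TOT": prec_tot,
        "SI": si,
    }
    for name, beta in coeffs.items():
        if name == "const":
            continue
        if name.startswith("w_"):
            surface = surface + beta * memb[int(name[2:]) - 1]
        else:
            surface = surface + beta * term_grids[name]
    # union of nodata masks over every input layer
    invalid = np.isnan(altitude.data) | np.isnan(months).any(axis=0) | np.isnan(memb).any(axis=0)
    return altitude.copy_with(np.where(invalid, np.nan, surface))


def predict_raster(
    model: ModelFit,
    altitude: Grid,
    climate: GridStack,
    membership: GridStack,
) -> IsoscapeRaster:
    """Apply a fitted model over covariate grids, with provenance."""
    surface = predict_surface(model.params, altitude, climate, membership)
    provenance = {
        "model": model.spec.label(),
        "n_fit": model.n,
        "terms": list(model.params.index),
        "grid_shape": list(altitude.data.shape),
        "cell_deg": altitude.cell,
    }
    return IsoscapeRaster(surface, provenance)


def summarize(raster: IsoscapeRaster, bins: int = 20) -> dict:
    """Min/max/mean and a histogram over unmasked cells only."""
    vals = raster.grid.data[~raster.mask]
    if vals.size == 0:
        raise IsoscapeError("fully masked raster: nothing to summarize")
    counts, edges = np.histogram(vals, bins=bins)
    return {
        "min": float(vals.min()),
        "max": float(vals.max()),
        "mean": float(vals.mean()),
        "n_cells": int(vals.size),
        "histogram": {"counts": counts.tolist(), "edges": edges.tolist()},
    }
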