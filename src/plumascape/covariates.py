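"""Per-sample covariate assembly and the collinearity screen.

Builds, for every specimen, the covariate row used by the regression
stage — absolute latitude, altitude (grid vs. label reconciliation),
annual precipitation, Walsh–Lawler seasonality, distance to the coast,
fuzzy region weights and the phenology-derived precipitation-δ²H
summaries — and screens continuous covariates for collinearity with a
Pearson correlation matrix.

The screen is rule-based rather than automatic: a declared retained
core (ABS_LAT, ALT, PREC_TOT, SI) is always kept, and the screened
candidates (NDVI, ET, DIST_SEA) are dropped when they correlate beyond
the threshold with a retained variable or with each other.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import Grid, GridStack
from .phenology import amount_weighted_d2h, moult_window, peak_month, seasonality_index

__all__ = [
    "CovariateError",
    "resolve_altitude",
    "distance_to_coast",
    "correlation_screen",
    "region_weights_at",
    "build_covariate_table",
    "RETAINED_CORE",
    "SCREEN_CANDIDATES",
]

EARTH_RADIUS_KM = 6371.0088
ALT_DISCORDANCE_M = 100.0  # grid/label disagreement beyond this: trust the label
RETAINED_CORE = ("ABS_LAT", "ALT", "PREC_TOT", "SI")
SCREEN_CANDIDATES = ("NDVI", "ET", "DIST_SEA")


class CovariateError(ValueError):
    pass


def resolve_altitude(
    grid_alt: float | None,
    label_alt: float | None,
    discordance_m: float = ALT_DISCORDANCE_M,
) -> float:
    """Reconcile DEM altitude with the specimen label's altitude.

    The grid value is authoritative unless the label disagrees by more
    than ``discordance_m`` metres, in which case the label wins (label
    data reflect the actual collection site within a coarse DEM cell).
    """
    grid_missing = grid_alt is None or np.isnan(grid_alt)
    label_missing = label_alt is None or np.isnan(label_alt)
    if grid_missing and label_missing:
        raise CovariateError("altitude missing from both grid and label")
    if grid_missing:
        return float(label_alt)
    if label_missing:
        return float(grid_alt)
    if abs(float(label_alt) - float(grid_alt)) > discordance_m:
        return float(label_alt)
    return float(grid_alt)


def _to_unit(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Lon/lat degrees to unit vectors, shape (..., 3)."""
    lam, phi = np.radians(lon), np.radians(lat)
    return np.stack(
        [np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)], axis=-1
    )


def _angle(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Great-circle angle between unit vectors (numerically stable)."""
    return np.arctan2(np.linalg.norm(np.cross(u, v), axis=-1), np.sum(u * v, axis=-1))


def distance_to_coast(lon: float, lat: float, coastline: np.ndarray) -> float:
    """Minimum great-circle distance (km) from a point to a coast polyline.

    ``coastline`` is an (n, 2) array of lon/lat vertices defining n−1
    segments (a single vertex is allowed).  For each segment the
    cross-track distance is used when the perpendicular foot lies
    within the segment; otherwise the nearer endpoint.
    """
    coastline = np.asarray(coastline, dtype=float)
    if coastline.ndim != 2 or coastline.shape[0] < 1 or coastline.shape[1] != 2:
        raise CovariateError("coastline must be a non-empty (n, 2) lon/lat array")
    p = _to_unit(np.array(lon), np.array(lat))
    verts = _to_unit(coastline[:, 0], coastline[:, 1])
    best = float(np.min(_angle(verts, p[None, :])))
    for a, b in zip(verts[:-1], verts[1:]):
        n = np.cross(a, b)
        norm = np.linalg.norm(n)
        if norm < 1e-12:  # degenerate segment
            continue
        n = n / norm
        # foot of the perpendicular on the segment's great circle
        foot = p - np.dot(p, n) * n
        fnorm = np.linalg.norm(foot)
        if fnorm < 1e-12:  # point at a pole of the great circle
            continue
        foot = foot / fnorm
        seg = _angle(a[None], b[None])[0]
        within = (
            _angle(a[None], foot[None])[0] + _angle(foot[None], b[None])[0]
            <= seg + 1e-9
        )
        if within:
            best = min(best, float(_angle(p[None], foot[None])[0]))
    return best * EARTH_RADIUS_KM


def correlation_screen(
    table: pd.DataFrame,
    threshold: float = 0.5,
    retained_core: tuple[str, ...] = RETAINED_CORE,
    candidates: tuple[str, ...] = SCREEN_CANDIDATES,
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Pearson collinearity screen over continuous covariates.

    Returns ``(retained, excluded, correlation_matrix)``.  A candidate
    is excluded when |r| > threshold against any retained-core variable
    or against another candidate (both members of a collinear candidate
    pair are dropped — neither can claim unique information).
    """
    if len(table) < 3:
        raise CovariateError("need at least 3 samples for a correlation screen")
    cols = [c for c in (*retained_core, *candidates) if c in table.columns]
    sub = table[cols].astype(float)
    zero_var = [c for c in cols if np.isclose(sub[c].std(ddof=0), 0.0)]
    if zero_var:
        raise CovariateError(f"zero-variance column(s): {', '.join(zero_var)}")
    corr = sub.corr(method="pearson")
    present_candidates = [c for c in candidates if c in cols]
    excluded = set()
    for c in present_candidates:
        for kept in retained_core:
            if kept in cols and abs(corr.loc[c, kept]) > threshold:
                excluded.add(c)
    for i, c1 in enumerate(present_candidates):
        for c2 in present_candidates[i + 1 :]:
            if abs(corr.loc[c1, c2]) > threshold:
                excluded.update((c1, c2))
    retained = [c for c in cols if c not in excluded]
    return retained, sorted(excluded), corr


def region_weights_at(membership: GridStack, lon: float, lat: float) -> np.ndarray:
    """Nearest-cell fuzzy region weights, renormalized after nodata.

    Bands that are nodata at the point are treated as weight 0 and the
    remainder rescaled to sum 1; all-band nodata is an error, not a
    silent zero vector.
    """
    w = membership.extract_at(lon, lat)
    valid = ~np.isnan(w)
    if not valid.any() or w[valid].sum() <= 0:
        raise CovariateError(f"no region membership available at ({lon}, {lat})")
    out = np.where(valid, w, 0.0)
    return out / out.sum()


def build_covariate_table(
    samples: pd.DataFrame,
    altitude: Grid,
    climate: GridStack,
    membership: GridStack,
    d2h_precip: GridStack | None = None,
    coastline: np.ndarray | None = None,
    discordance_m: float = ALT_DISCORDANCE_M,
) -> pd.DataFrame:
    """Assemble the full per-sample covariate table.

    ``samples`` needs ``lon``/``lat`` (plus optional ``alt_label`` and
    a ``d2h`` response, which are carried through).  All raster lookups
    are nearest-cell.  When a monthly precipitation-δ²H stack is given,
    the amount-weighted annual, moult-month and moult-season δ²H
    summaries are added; when a coastline is given, DIST_SEA is added.
    """
    rows = []
    months12 = climate.as_array()  # (12, nrows, ncols)
    for rec in samples.to_dict("records"):
        lon, lat = float(rec["lon"]), float(rec["lat"])
        r, c = climate.grid.index_of(lon, lat)
        precip = months12[:, r, c]
        grid_alt = altitude.data[altitude.index_of(lon, lat)]
        label_alt = rec.get("alt_label", np.nan)
        row = {
            "lon": lon,
            "lat": lat,
            "ABS_LAT": abs(lat),
            "ALT": resolve_altitude(grid_alt, label_alt, discordance_m),
            "PREC_TOT": float(precip.sum()),
            "SI": seasonality_index(precip),
        }
        window = moult_window(precip)
        row["peak_month"] = peak_month(precip)
        row["moult_month"] = window.month
        if d2h_precip is not None:
            d2h_months = d2h_precip.extract_at(lon, lat)
            row["d2h_precip_annual"] = amount_weighted_d2h(precip, d2h_months)
            row["d2h_precip_moult_month"] = amount_weighted_d2h(
                precip, d2h_months, [window.month]
            )
            row["d2h_precip_moult_season"] = amount_weighted_d2h(
                precip, d2h_months, window.season
            )
        if coastline is not None:
            row["DIST_SEA"] = distance_to_coast(lon, lat, coastline)
        weights = region_weights_at(membership, lon, lat)
        for i, w in enumerate(weights):
            row[f"w_{i + 1}"] = w
        for passthrough in ("id", "d2h", "country", "locality", "collection_year"):
            if passthrough in rec:
                row[passthrough] = rec[passthrough]
        rows.append(row)
    return pd.DataFrame(rows)
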