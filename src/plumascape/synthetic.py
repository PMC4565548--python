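"""Self-contained synthetic world with known ground truth.

Real feather-isoscape construction needs continental climate rasters,
an altitude model, a precipitation-δ²H surface, a fuzzy climatic
regionalization and a museum specimen table.  This module fabricates
all of them on a desk-scale lattice from a single seed, with the
generating linear model known exactly, so that every downstream stage
— covariate extraction, model selection, raster prediction, isoscape
comparison — can be verified against truth.

The world emulates a sub-Saharan-Africa-like domain by default
(lon −20..52°, lat −35..20°, 1° cells): spatially smooth altitude,
annual-rainfall, seasonality-strength and precipitation-δ²H fields;
a peak-rain month that drifts with latitude (monsoon-like); six
spatially coherent fuzzy regions; and feather δ²H generated as

    δ²H = β₀ + β_lat·|lat| + β_lat²·lat² + β_alt·ALT + β_prec·PREC_TOT
          + β_si·SI + Σ_{r=2..6} w_r·β_r + ε,   ε ~ N(0, σ²),

with coefficient magnitudes typical of a continental feather-δ²H
regression and measurement noise σ = 3‰ by default.  The default
specimen table mirrors a museum-collection sampling structure:
224 specimens at 205 distinct localities across 34 countries.

Monthly rainfall at a pixel is a mixture of a uniform regime and a
truncated-cosine bump centred on the peak month; the seasonality
strength ``s`` interpolates from uniform (``s = 0``, Walsh–Lawler
SI = 0) to all rain in the peak month (``s = 1``, SI = 22/12), so the
generator spans the full seasonality-classification range.

Randomness: one global seed; each grid and the sampling/noise draws use
independent sub-streams derived from (seed, fixed offset), so any grid
can be regenerated alone, bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .calibration import DEFAULT_ACCEPTED, KeratinStandard
from .grids import Grid, GridStack
from .phenology import seasonality_index

__all__ = [
    "TrueCoefficients",
    "WorldConfig",
    "WorldGrids",
    "TruthBundle",
    "generate_world",
    "generate_climate",
    "generate_regions",
    "generate_samples",
    "generate_specimen_table",
    "generate_standard_runs",
    "make_prior_isoscape",
]

# Fixed sub-stream offsets (one per independent random component).
_STREAMS = {
    "altitude": 11,
    "annual_total": 13,
    "strength": 17,
    "peak": 19,
    "d2h_base": 23,
    "d2h_amp": 29,
    "regions": 31,
    "samples": 37,
    "noise": 41,
    "countries": 43,
    "standards": 47,
    "prior": 53,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass(frozen=True)
class TrueCoefficients:
    """Generating coefficients of the feather-δ²H linear model.

    Units: intercept ‰; abs_lat ‰/°; abs_lat2 ‰/°²; alt ‰/m;
    prec_tot ‰/mm·yr⁻¹; si ‰ per index unit; region ‰ offsets for
    regions 2..n against region 1 (baseline).  Defaults are of the
    magnitude reported for continental feather-δ²H regressions.
    """

    intercept: float = 4.785867
    abs_lat: float = -0.481181
    abs_lat2: float = 0.024396
    alt: float = 0.003328
    prec_tot: float = -0.008978
    si: float = -14.578157
    region: tuple[float, ...] = (
        -14.103769,
        -25.349481,
        -17.133694,
        -27.852456,
        -25.3549,
    )

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        """Evaluate the generating model on a covariate table.

        Expects columns ABS_LAT, ALT, PREC_TOT, SI and region weights
        w_1..w_n; the baseline region (w_1) contributes zero.
        """
        out = (
            self.intercept
            + self.abs_lat * table["ABS_LAT"].to_numpy()
            + self.abs_lat2 * table["ABS_LAT"].to_numpy() ** 2
            + self.alt * table["ALT"].to_numpy()
            + self.prec_tot * table["PREC_TOT"].to_numpy()
            + self.si * table["SI"].to_numpy()
        )
        for r, beta in enumerate(self.region, start=2):
            out = out + beta * table[f"w_{r}"].to_numpy()
        return out


@dataclass
class WorldConfig:
    """Parameters of the synthetic world."""

    lon_min: float = -20.0
    lon_max: float = 52.0
    lat_min: float = -35.0
    lat_max: float = 20.0
    cell: float = 1.0
    n_regions: int = 6
    seed: int = 0
    sigma: float = 3.0  # ‰, feather measurement noise
    alt_range: tuple[float, float] = (0.0, 3000.0)  # m
    prec_range: tuple[float, float] = (150.0, 2800.0)  # mm/yr
    strength_range: tuple[float, float] = (0.05, 0.95)  # seasonality strength
    d2h_base_range: tuple[float, float] = (-60.0, 10.0)  # ‰, precip δ²H annual mean
    d2h_amp_range: tuple[float, float] = (2.0, 15.0)  # ‰, seasonal amplitude
    smoothness: float = 6.0  # gaussian-filter sigma, in cells
    region_temperature: float = 8.0  # degrees; softmax temperature
    coefficients: TrueCoefficients = field(default_factory=TrueCoefficients)

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise ValueError("cell size must be positive")
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ValueError("degenerate extent")
        if self.n_regions < 2:
            raise ValueError("at least two regions required")
        if self.sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if len(self.coefficients.region) != self.n_regions - 1:
            raise ValueError(
                f"need {self.n_regions - 1} region coefficients, "
                f"got {len(self.coefficients.region)}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        nrows = int(round((self.lat_max - self.lat_min) / self.cell))
        ncols = int(round((self.lon_max - self.lon_min) / self.cell))
        return nrows, ncols

    def empty_grid(self, fill: float = 0.0) -> Grid:
        nrows, ncols = self.shape
        return Grid(np.full((nrows, ncols), fill), self.lon_min, self.lat_max, self.cell)


def _smooth_field(config: WorldConfig, stream: str, lo: float, hi: float) -> np.ndarray:
    """Spatially smooth random field rescaled to [lo, hi]."""
    rng = _rng(config.seed, stream)
    noise = rng.standard_normal(config.shape)
    smooth = gaussian_filter(noise, sigma=config.smoothness, mode="reflect")
    span = np.ptp(smooth)
    if span == 0:  # degenerate 1-cell grid
        return np.full(config.shape, 0.5 * (lo + hi))
    return lo + (hi - lo) * (smooth - smooth.min()) / span


@dataclass
class WorldGrids:
    """All generated truth grids of one synthetic world."""

    altitude: Grid
    annual_total: Grid
    strength: Grid
    peak: Grid  # integer months 1..12
    climate: GridStack  # 12 monthly precipitation layers, mm
    d2h: GridStack  # 12 monthly precipitation δ²H layers, ‰
    regions: GridStack  # n_regions fuzzy membership layers, simplex per pixel
    region_centers: np.ndarray  # (n_regions, 2) lon/lat
    si: Grid  # Walsh–Lawler index derived from the climate stack


def _monthly_weights(peak: np.ndarray, strength: np.ndarray) -> np.ndarray:
    """Per-pixel monthly rainfall fractions, shape (12, ...).

    Mixture of a uniform regime and a truncated-cosine bump whose
    half-width shrinks with the strength ``s``: at s = 1 the bump is a
    single month, at s = 0 the mixture is uniform.  Fractions sum to 1,
    and for s > 0 the strict argmax is the configured peak month.
    """
    months = np.arange(1, 13).reshape((12,) + (1,) * peak.ndim)
    delta = np.abs(months - peak[None, ...])
    d = np.minimum(delta, 12 - delta)  # circular month distance, 0..6
    half_width = 1.0 + 5.0 * (1.0 - strength)[None, ...]
    bump = np.where(d < half_width, np.cos(np.pi * d / (2.0 * half_width)), 0.0)
    bump = bump / bump.sum(axis=0, keepdims=True)
    return (1.0 - strength)[None, ...] / 12.0 + strength[None, ...] * bump


def generate_climate(config: WorldConfig) -> GridStack:
    """12 monthly precipitation grids (mm) with configured totals/peaks.

    The per-pixel annual sum equals the annual-total field exactly and
    the wettest month equals the peak-month field wherever the
    seasonality strength is positive.
    """
    world = _climate_fields(config)
    return world[0]


def _climate_fields(config: WorldConfig) -> tuple[GridStack, Grid, Grid, Grid]:
    template = config.empty_grid()
    total = _smooth_field(config, "annual_total", *config.prec_range)
    strength = _smooth_field(config, "strength", *config.strength_range)
    # Peak month drifts with latitude (monsoon-like): smooth noise + trend.
    lat = template.lat_centers()[:, None] * np.ones(config.shape)
    drift = (lat - lat.min()) / max(np.ptp(lat), 1e-12) * 8.0
    jitter = _smooth_field(config, "peak", 0.0, 4.0)
    peak = (np.floor(drift + jitter) % 12 + 1).astype(float)
    weights = _monthly_weights(peak, strength)
    bands = [template.copy_with(total * weights[m]) for m in range(12)]
    stack = GridStack(bands, labels=[f"month_{m:02d}" for m in range(1, 13)])
    return (
        stack,
        template.copy_with(total),
        template.copy_with(strength),
        template.copy_with(peak),
    )


def _generate_d2h(config: WorldConfig, peak: Grid) -> GridStack:
    """Monthly precipitation-δ²H stack: smooth annual mean, seasonal cycle.

    The cycle is phase-locked to the rain peak and depleted in the wet
    season (an amount-effect caricature)."""
    base = _smooth_field(config, "d2h_base", *config.d2h_base_range)
    amp = _smooth_field(config, "d2h_amp", *config.d2h_amp_range)
    template = config.empty_grid()
    bands = []
    for m in range(1, 13):
        phase = 2.0 * np.pi * (m - peak.data) / 12.0
        bands.append(template.copy_with(base - amp * np.cos(phase)))
    return GridStack(bands, labels=[f"month_{m:02d}" for m in range(1, 13)])


def generate_regions(config: WorldConfig, one_hot: bool = False) -> tuple[GridStack, np.ndarray]:
    """Fuzzy membership weights over ``n_regions`` climatic regions.

    Region centers are drawn inside the extent; per-pixel weights are a
    softmax of negative distances to the centers with a temperature
    parameter, hence smooth, in [0, 1] and summing to 1 everywhere.
    ``one_hot=True`` (the zero-temperature limit) assigns each pixel
    entirely to its nearest region.
    """
    rng = _rng(config.seed, "regions")
    centers = np.column_stack(
        [
            rng.uniform(config.lon_min, config.lon_max, config.n_regions),
            rng.uniform(config.lat_min, config.lat_max, config.n_regions),
        ]
    )
    template = config.empty_grid()
    lon = template.lon_centers()[None, :] * np.ones(config.shape)
    lat = template.lat_centers()[:, None] * np.ones(config.shape)
    dists = np.stack(
        [np.hypot(lon - cx, lat - cy) for cx, cy in centers], axis=0
    )  # (n_regions, nrows, ncols), degrees
    if one_hot:
        nearest = np.argmin(dists, axis=0)
        weights = np.stack(
            [(nearest == r).astype(float) for r in range(config.n_regions)], axis=0
        )
    else:
        logits = -dists / config.region_temperature
        logits -= logits.max(axis=0, keepdims=True)
        expd = np.exp(logits)
        weights = expd / expd.sum(axis=0, keepdims=True)
    bands = [template.copy_with(weights[r]) for r in range(config.n_regions)]
    stack = GridStack(bands, labels=[f"region_{r + 1}" for r in range(config.n_regions)])
    return stack, centers


def generate_world(config: WorldConfig, one_hot_regions: bool = False) -> WorldGrids:
    """Generate every truth grid of the synthetic world."""
    climate, total, strength, peak = _climate_fields(config)
    alt = config.empty_grid().copy_with(_smooth_field(config, "altitude", *config.alt_range))
    d2h = _generate_d2h(config, peak)
    regions, centers = generate_regions(config, one_hot=one_hot_regions)
    si = config.empty_grid().copy_with(seasonality_index(climate.as_array(), axis=0))
    return WorldGrids(
        altitude=alt,
        annual_total=total,
        strength=strength,
        peak=peak,
        climate=climate,
        d2h=d2h,
        regions=regions,
        region_centers=centers,
        si=si,
    )


@dataclass
class TruthBundle:
    """Ground truth accompanying a generated sample table."""

    config: WorldConfig
    grids: WorldGrids
    coefficients: TrueCoefficients
    covariates: pd.DataFrame  # true covariate values at the sample pixels
    noiseless: np.ndarray  # linear predictor before measurement noise


def _covariates_at_pixels(
    world: WorldGrids, rows: np.ndarray, cols: np.ndarray, config: WorldConfig
) -> pd.DataFrame:
    grid = world.altitude
    lons = grid.lon_centers()[cols]
    lats = grid.lat_centers()[rows]
    table = pd.DataFrame(
        {
            "lon": lons,
            "lat": lats,
            "ABS_LAT": np.abs(lats),
            "ALT": world.altitude.data[rows, cols],
            "PREC_TOT": world.annual_total.data[rows, cols],
            "SI": world.si.data[rows, cols],
        }
    )
    memb = world.regions.as_array()
    for r in range(config.n_regions):
        table[f"w_{r + 1}"] = memb[r, rows, cols]
    return table


def generate_samples(
    config: WorldConfig,
    n: int,
    world: WorldGrids | None = None,
    noise_stream: int | None = None,
) -> tuple[pd.DataFrame, TruthBundle]:
    """Draw ``n`` specimens at random grid cells with modeled δ²H.

    Sample coordinates are cell centers (locality accuracy below the
    cell size carries no information at this resolution), so covariate
    extraction reproduces the generator's truth exactly.  The observed
    value is the linear predictor plus N(0, σ²) noise; the returned
    :class:`TruthBundle` keeps the noiseless values.

    ``noise_stream`` offsets the sampling/noise sub-streams so that
    replicate designs can be drawn from one world without regenerating
    the grids.
    """
    if n < 1:
        raise ValueError("at least one sample required")
    if world is None:
        world = generate_world(config)
    extra = 0 if noise_stream is None else int(noise_stream)
    rng_s = np.random.default_rng([config.seed, _STREAMS["samples"], extra])
    rng_e = np.random.default_rng([config.seed, _STREAMS["noise"], extra])
    nrows, ncols = config.shape
    flat = rng_s.integers(0, nrows * ncols, size=n)
    rows, cols = np.divmod(flat, ncols)
    cov = _covariates_at_pixels(world, rows, cols, config)
    noiseless = config.coefficients.linear_predictor(cov)
    observed = noiseless + rng_e.normal(0.0, config.sigma, size=n)
    samples = pd.DataFrame(
        {
            "id": [f"S{i + 1:04d}" for i in range(n)],
            "lon": cov["lon"],
            "lat": cov["lat"],
            "d2h": observed,
        }
    )
    truth = TruthBundle(config, world, config.coefficients, cov, noiseless)
    return samples, truth


# --- museum specimen table ------------------------------------------------

# Default sampling structure of a continental museum-collection study:
# specimens, distinct localities and countries covered.
DEFAULT_N_SPECIMENS = 224
DEFAULT_N_LOCALITIES = 205
DEFAULT_N_COUNTRIES = 34

# Synthetic "instrument": raw within-run values relate to VSMOW by this
# affine map; the calibration stage must recover it from the standards.
INSTRUMENT_SLOPE = 0.94
INSTRUMENT_INTERCEPT = -11.5
STANDARD_RUN_SD = 1.2  # ‰, replicate scatter of standard measurements


def generate_standard_runs(
    config: WorldConfig, n_replicates: int = 5
) -> list[KeratinStandard]:
    """Replicate raw measurements of the three keratin standards.

    Raw values are the accepted values pushed through the inverse of
    the synthetic instrument map plus replicate noise, so fitting the
    comparative-equilibration line recovers the instrument map.
    """
    rng = _rng(config.seed, "standards")
    out = []
    for name, accepted in DEFAULT_ACCEPTED.items():
        raw_center = (accepted - INSTRUMENT_INTERCEPT) / INSTRUMENT_SLOPE
        reps = raw_center + rng.normal(0.0, STANDARD_RUN_SD, size=n_replicates)
        out.append(KeratinStandard(name, accepted, tuple(reps)))
    return out


def generate_specimen_table(
    config: WorldConfig,
    n_specimens: int = DEFAULT_N_SPECIMENS,
    n_localities: int = DEFAULT_N_LOCALITIES,
    n_countries: int = DEFAULT_N_COUNTRIES,
    world: WorldGrids | None = None,
) -> tuple[pd.DataFrame, TruthBundle]:
    """A museum-style specimen table with locality/country structure.

    ``n_localities`` distinct grid cells are drawn; each is assigned to
    the nearest of ``n_countries`` country seed points (the first
    localities sit on the seeds themselves, so every country appears).
    Specimens cover every locality once, with the remainder resampled
    from the locality list, mimicking multi-specimen localities.  The
    table carries raw instrument-scale δ²H (``d2h_raw``) plus label
    altitude for a subset and a collection year in 1950–2014.
    """
    if not 1 <= n_countries <= n_localities <= n_specimens:
        raise ValueError("need n_countries <= n_localities <= n_specimens")
    if world is None:
        world = generate_world(config)
    rng = _rng(config.seed, "samples")
    rng_c = _rng(config.seed, "countries")
    rng_e = _rng(config.seed, "noise")
    nrows, ncols = config.shape
    if n_localities > nrows * ncols:
        raise ValueError("more localities than grid cells")

    country_seeds = np.column_stack(
        [
            rng_c.uniform(config.lon_min, config.lon_max, n_countries),
            rng_c.uniform(config.lat_min, config.lat_max, n_countries),
        ]
    )
    template = world.altitude
    # first n_countries localities: the cells containing the country seeds
    seed_cells = [template.index_of(lon, lat) for lon, lat in country_seeds]
    chosen: dict[tuple[int, int], None] = dict.fromkeys(seed_cells)
    while len(chosen) < n_localities:
        flat = int(rng.integers(0, nrows * ncols))
        chosen.setdefault(divmod(flat, ncols), None)
    loc_rows = np.array([rc[0] for rc in chosen])
    loc_cols = np.array([rc[1] for rc in chosen])
    loc_lons = template.lon_centers()[loc_cols]
    loc_lats = template.lat_centers()[loc_rows]
    d_to_seed = np.hypot(
        loc_lons[:, None] - country_seeds[None, :, 0],
        loc_lats[:, None] - country_seeds[None, :, 1],
    )
    loc_country = np.argmin(d_to_seed, axis=1)

    # every locality once, then resample the remainder (multi-specimen sites)
    extra = rng.integers(0, n_localities, size=n_specimens - n_localities)
    loc_idx = np.concatenate([np.arange(n_localities), extra])

    cov = _covariates_at_pixels(world, loc_rows[loc_idx], loc_cols[loc_idx], config)
    noiseless = config.coefficients.linear_predictor(cov)
    observed = noiseless + rng_e.normal(0.0, config.sigma, size=n_specimens)
    raw = (observed - INSTRUMENT_INTERCEPT) / INSTRUMENT_SLOPE

    has_label_alt = rng.random(n_specimens) < 0.3
    label_alt = np.where(has_label_alt, np.round(cov["ALT"].to_numpy(), -1), np.nan)
    table = pd.DataFrame(
        {
            "id": [f"F{i + 1:04d}" for i in range(n_specimens)],
            "lon": cov["lon"],
            "lat": cov["lat"],
            "locality": [f"L{j + 1:03d}" for j in loc_idx],
            "country": [f"C{loc_country[j] + 1:02d}" for j in loc_idx],
            "collection_year": rng.integers(1950, 2015, size=n_specimens),
            "alt_label": label_alt,
            "d2h_raw": raw,
        }
    )
    truth = TruthBundle(config, world, config.coefficients, cov, noiseless)
    return table, truth


def make_prior_isoscape(config: WorldConfig, truth_raster: Grid) -> Grid:
    """A synthetic 'previously published' isoscape for comparison tests.

    The truth surface plus a smooth regional bias field (±12‰) and a
    constant offset — structured disagreement, as between two isoscapes
    built from different source data, not white noise.
    """
    bias = _smooth_field(config, "prior", -12.0, 12.0)
    return truth_raster.copy_with(truth_raster.data + bias + 4.0)
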