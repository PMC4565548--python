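# Methods

This note documents the models, defaults and design choices behind
plumascape, in the order the pipeline runs them.

## Calibration (raw → VSMOW)

Non-exchangeable hydrogen in keratin exchanges with ambient water
vapour, so raw instrument values are mapped to the VSMOW scale by
comparative equilibration: keratin standards measured in the same run
define an affine map fitted by ordinary least squares from each
standard's **mean** measured value to its accepted value (CBS −197‰,
KHS −54.1‰, LIE-PA2 +20.8‰). We deliberately fit on standard means
rather than replicate-weighted values: replicate counts vary by run
and are often unreported, and the per-standard residuals are exposed
for quality control instead. A run is flagged when any residual
exceeds 3‰, the nominal within-run measurement error. With two
standards the map is exact; three or more give a genuine least-squares
fit. Drift within runs and the physics of H-exchange are out of scope.

## Rainfall phenology

For a sedentary tropical insectivore, moult is assumed to follow
breeding, which tracks the rains. From the 12 monthly precipitation
values at a locality (months indexed 1–12, circular):

* **peak month** — argmax of monthly rainfall; ties break to the
  earliest calendar month (a deterministic rule; ties are measure-zero
  in real data but common in synthetic regimes);
* **moult month** — peak + 2 (mod 12);
* **moult season** — the four months peak+1 … peak+4 (mod 12). We read
  "the months after the peak" literally (season starts the month
  *after* the peak, not at the peak). A variant that truncates the
  season at dry-season onset would be a one-line change; it is not
  implemented because onset is not well defined for weakly seasonal
  pixels.
* **Walsh–Lawler seasonality** SI = (1/R)·Σ|xₙ − R/12|, bounded by 0
  (uniform) and 22/12 (single-month rainfall); SI < 0.19 is "spread
  through the year", SI > 1.2 "extreme". SI is scale-invariant, so it
  separates rainfall *shape* from amount (PREC_TOT).
* **amount-weighted δ²H** over a window: Σ pₘδₘ / Σ pₘ. A window with
  zero rain raises an error rather than returning a silent 0 — an
  unweightable window is a data problem the user must see.

Bimodal rainfall regimes use the single global maximum; no
secondary-peak handling is attempted.

## Covariates and the collinearity screen

Raster lookups are **nearest-cell, no interpolation**: museum locality
accuracy (order 10 km) does not support sub-cell precision, and
nearest-cell extraction is reproducible and order-independent.
Altitude reconciles two sources: the DEM value wins unless the
specimen label's altitude differs by more than 100 m (default), in
which case the label wins — label data reflect the actual collection
site within a coarse DEM cell. Distance to coast is the minimum
great-circle distance (mean Earth radius 6371.0088 km) from the point
to a coastline polyline, using cross-track distance where the
perpendicular foot lies on a segment and endpoint distance otherwise.

The Pearson screen is rule-based, not an automatic VIF search: the
retained core {ABS_LAT, ALT, PREC_TOT, SI} is never dropped, and the
screened candidates {NDVI, ET, DIST_SEA} are excluded when |r| exceeds
the threshold (default 0.5) against a retained variable **or** against
another candidate (a mutually collinear candidate pair carries no
attributable information, so both are dropped). The threshold and the
retained core are arguments, because the exclusion decision is
ultimately a judgment call that should be visible and overridable.

## Model selection

Candidates are all subsets of {ALT, PREC_TOT, SI, ABS_LAT-block,
REGION}: the latitude block has three states (absent, linear,
linear+quadratic — marginality forbids the quadratic alone) and REGION
enters as an all-or-nothing block of five weight columns w₂…w₆ against
the baseline region 1, giving 2⁴·3 = 48 models including
intercept-only. Because the fuzzy membership weights sum to 1, the
"dummies" are the weights themselves: a sample fully inside region r
reproduces the classical 0/1 factor coding, and fuzzy samples blend
the regional offsets linearly — the same arithmetic the prediction
stage uses, so fitting and mapping are consistent by construction.

AICc uses the Gaussian maximum-likelihood log-likelihood with
k = intercept + slopes + residual variance (the standard convention
for Gaussian OLS, stated explicitly because "AICc" alone is
ambiguous); AICc = AIC + 2k(k+1)/(n−k−1). Akaike weights are
normalized over the full candidate set; the "supported set" is
ΔAICc < 2; a block's relative importance is the summed weight of
models containing it. Confidence intervals are t-based at 95% by
default. Prediction uses the single top-ranked model; model averaging
is deliberately out of scope. OLS itself is delegated to statsmodels;
the AICc bookkeeping, enumeration, ranking and importance layers are
this package's.

## Isoscape prediction

The selected coefficients are evaluated at every cell:
δ²H = β₀ + Σβⱼxⱼ + Σ_{r≥2} w_r β_r. SI and PREC_TOT are derived
per pixel from the same monthly stack the phenology stage uses (one
source of truth); ABS_LAT comes from cell-center latitudes. All input
grids must share one lattice exactly — a mismatch raises instead of
silently resampling. The output mask is the union of the input nodata
masks, and the map is the fixed-effects surface only (no residual
kriging, no back-transform).

## Comparison

Two isoscapes are compared on the coarser lattice: block-mean
aggregation assigns each fine cell (by center) to the coarse cell
containing it and averages unmasked members (nearest-cell aggregation
is available as an alternative). The per-pixel mismatch is the
standard deviation of the two values, sample convention |a−b|/√2 by
default (population |a−b|/2 via a flag — with n = 2 the choice is a
convention, so both are offered). Observed feather values regress on
extracted predictions by simple OLS with F on (1, n−2) df; samples on
masked cells are dropped, never imputed.

## The synthetic world

The generator emulates the study conditions of a continental
museum-collection isoscape on a sub-Saharan-Africa-like extent
(lon −20…52°, lat −35…20°, 1° cells by default):

* smooth random fields (seeded Gaussian noise, Gaussian-filtered with
  σ = 6 cells, rescaled) for altitude (0–3000 m), annual rainfall
  (150–2800 mm), seasonality strength (0.05–0.95), precipitation-δ²H
  annual mean (−60…+10‰) and seasonal amplitude (2–15‰);
* monthly rainfall per pixel as a mixture of a uniform regime and a
  truncated-cosine bump centred on the peak month, whose half-width
  shrinks with the strength s: s = 0 is exactly uniform (SI = 0) and
  s = 1 puts all rain in the peak month (SI = 22/12), so the full
  seasonality-classification range is reachable; the peak month drifts
  with latitude, monsoon-like;
* six fuzzy regions as a softmax of negative distances to random
  region centers (temperature 8°; the zero-temperature limit is the
  one-hot hard regionalization, available directly);
* feather δ²H from the known linear model with measurement noise
  σ = 3‰ (the nominal run error), coefficient defaults of the
  magnitude seen in continental feather-δ²H regressions;
* a specimen table with museum structure — 224 specimens at 205
  distinct localities in 34 countries (localities seeded so every
  country appears; surplus specimens resample localities, mimicking
  multi-specimen sites), collection years 1950–2014, raw values on a
  synthetic instrument scale (slope 0.94, intercept −11.5‰) with
  replicate standard runs so the calibration stage has real work to
  do; label altitudes exist for ~30% of specimens.

Randomness uses one global seed with fixed per-component sub-streams,
so any grid regenerates alone, bit-identically. Sample coordinates are
cell centers: at 1° resolution, sub-cell locality error carries no
information, and this makes covariate extraction exactly invertible
against truth — the basis of the zero-noise closure tests.

What the synthetic world does **not** emulate: real African climate
(no orography, no coherent monsoon dynamics beyond the latitude
drift), spatial autocorrelation of measurement error, taxon effects,
collection-date effects, or the real fuzzy regionalization's
shapes. Passing tests therefore demonstrate that the *pipeline
arithmetic* is correct and that the statistical machinery recovers
known truth under realistic noise — not that any particular real-world
isoscape is accurate. The synthetic "prior" isoscape used by the
comparison stage is the truth surface plus a smooth ±12‰ bias field
and a +4‰ offset (structured disagreement, labelled synthetic).

## Numerical choices and problem sizes

Nodata is NaN internally and an explicit `NODATA_value` on disk
(ESRI ASCII grids, a plain-text raster format every GIS reads).
Out-of-extent lookups raise; nodata propagates. Simplex weights are
validated to 1e-6 at prediction and regenerated exactly on the
simplex. Rank deficiency is detected by matrix rank before fitting
and reported with the offending term list.

Test and verification sizes: zero-noise closure at n = 250–300;
parameter recovery at 200 replicates of n = 500 with σ = 3‰ (about
25 s total — each replicate refits all 48 candidates); the full study
fit at n = 224, chosen as the canonical museum-collection sample
size. The recovery study checks that estimates fall within 2 SEs of
truth ≥ 93% of the time per coefficient, that mean t-CI coverage sits
at the nominal 95% within binomial tolerance, and that the generating
model stays in the ΔAICc < 2 set ≥ 80% of the time.

## Known limitations

* No reprojection: everything is WGS84 lon/lat, north-up.
* Degree-based (not area-true) block aggregation in `resample`;
  adequate for like-with-like isoscape comparison, not for flux
  accounting.
* The correlation screen is pairwise; it will not catch a covariate
  collinear only with a *combination* of retained variables (the
  rank check at fit time will).
* No geographic assignment of unknown-origin birds (likelihood
  surfaces, odds ratios): the pipeline stops at the isoscape.
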