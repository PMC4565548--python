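"""Pixel prediction, raster application and region-weight blending."""

import numpy as np
import pandas as pd
import pytest

from plumascape.grids import Grid, GridStack
from plumascape.isoscape import (
    IsoscapeError,
    predict_pixel,
    predict_raster,
    predict_surface,
    summarize,
)
from plumascape.modeling import FULL_MODEL, fit_ols
from plumascape.pipeline import _truth_coeff_mapping
from plumascape.synthetic import WorldConfig, generate_samples

# Coefficients of a continental feather-δ²H model (‰-scale magnitudes)
COEFFS = {
    "const": 4.785867,
    "ABS_LAT2": 0.024396,
    "ABS_LAT": -0.481181,
    "ALT": 0.003328,
    "PREC_TOT": -0.008978,
    "SI": -14.578157,
    "w_2": -14.103769,
    "w_3": -25.349481,
    "w_4": -17.133694,
    "w_5": -27.852456,
    "w_6": -25.3549,
}
ZERO_COV = {"ABS_LAT": 0.0, "ALT": 0.0, "PREC_TOT": 0.0, "SI": 0.0}


class TestPredictPixel:
    def test_baseline_region_all_zero_covariates_gives_intercept(self):
        w = [1, 0, 0, 0, 0, 0]
        assert predict_pixel(COEFFS, ZERO_COV, w) == pytest.approx(4.785867)

    def test_full_weight_on_one_region_adds_its_offset(self):
        w = [0, 0, 0, 0, 1, 0]  # region 5
        assert predict_pixel(COEFFS, ZERO_COV, w) == pytest.approx(
            4.785867 - 27.852456, abs=1e-9
        )

    def test_half_half_blend_is_linear(self):
        w = [0.5, 0, 0, 0, 0.5, 0]
        assert predict_pixel(COEFFS, ZERO_COV, w) == pytest.approx(
            4.785867 - 13.926228, abs=1e-9
        )

    def test_quadratic_term_derived_from_abs_lat(self):
        cov = dict(ZERO_COV, ABS_LAT=10.0)
        expected = 4.785867 - 0.481181 * 10 + 0.024396 * 100
        assert predict_pixel(COEFFS, cov, [1, 0, 0, 0, 0, 0]) == pytest.approx(expected)

    def test_off_simplex_weights_rejected(self):
        with pytest.raises(IsoscapeError):
            predict_pixel(COEFFS, ZERO_COV, [0.7, 0.7, 0, 0, 0, 0])

    def test_nan_covariate_masks_output(self):
        cov = dict(ZERO_COV, ALT=np.nan)
        assert np.isnan(predict_pixel(COEFFS, cov, [1, 0, 0, 0, 0, 0]))


def constant_world(alt=500.0, prec=100.0, nrows=3, ncols=4):
    g = Grid(np.full((nrows, ncols), alt), 0.0, 0.0, 1.0)
    climate = GridStack([g.copy_with(np.full((nrows, ncols), prec))] * 12,
                        labels=[f"month_{m:02d}" for m in range(1, 13)])
    memb = GridStack(
        [g.copy_with(np.ones((nrows, ncols)))]
        + [g.copy_with(np.zeros((nrows, ncols))) for _ in range(5)],
        labels=[f"region_{r}" for r in range(1, 7)],
    )
    return g, climate, memb


class TestPredictSurface:
    def test_constant_grids_give_constant_raster(self):
        alt, climate, memb = constant_world()
        surface = predict_surface(COEFFS, alt, climate, memb)
        lat = alt.lat_centers()[0]  # rows share |lat| only along a row
        expected = predict_pixel(
            COEFFS,
            {"ABS_LAT": abs(alt.lat_centers()[1]), "ALT": 500.0,
             "PREC_TOT": 1200.0, "SI": 0.0},
            [1, 0, 0, 0, 0, 0],
        )
        assert surface.data[1, 0] == pytest.approx(expected, abs=1e-9)
        assert np.ptp(surface.data[1]) == pytest.approx(0.0, abs=1e-12)

    def test_reproduces_generator_noiseless_field(self, world_cfg, world):
        """Closure: the truth surface evaluated at sample pixels equals the
        generator's noiseless values."""
        surface = predict_surface(
            _truth_coeff_mapping(world_cfg), world.altitude, world.climate, world.regions
        )
        samples, truth = generate_samples(world_cfg, 50, world=world)
        at_samples = np.array(
            [surface.extract_at(lon, lat) for lon, lat in zip(samples["lon"], samples["lat"])]
        )
        np.testing.assert_allclose(at_samples, truth.noiseless, atol=1e-9)

    def test_nodata_input_cell_masked_in_output(self):
        alt, climate, memb = constant_world()
        alt.data[1, 2] = np.nan
        surface = predict_surface(COEFFS, alt, climate, memb)
        assert np.isnan(surface.data[1, 2])
        assert np.isfinite(surface.data[0, 0])

    def test_misregistered_grids_rejected(self):
        alt, climate, memb = constant_world()
        shifted = Grid(alt.data.copy(), alt.west + 0.5, alt.north, alt.cell)
        with pytest.raises(IsoscapeError, match="co-registered"):
            predict_surface(COEFFS, shifted, climate, memb)

    def test_prediction_is_deterministic(self, world_cfg, world):
        a = predict_surface(_truth_coeff_mapping(world_cfg), world.altitude,
                            world.climate, world.regions)
        b = predict_surface(_truth_coeff_mapping(world_cfg), world.altitude,
                            world.climate, world.regions)
        np.testing.assert_array_equal(a.data, b.data)

    def test_one_hot_limit_equals_dummy_prediction(self):
        alt, climate, memb_soft = constant_world()
        one_hot = GridStack(
            [alt.copy_with(np.zeros(alt.data.shape)) for _ in range(6)],
            labels=memb_soft.labels,
        )
        one_hot.bands[4].data[:] = 1.0  # every pixel fully region 5
        surface = predict_surface(COEFFS, alt, climate, one_hot)
        row = 1
        expected = predict_pixel(
            COEFFS,
            {"ABS_LAT": abs(alt.lat_centers()[row]), "ALT": 500.0,
             "PREC_TOT": 1200.0, "SI": 0.0},
            [0, 0, 0, 0, 1, 0],
        )
        assert surface.data[row, 0] == pytest.approx(expected, abs=1e-9)


class TestPredictRasterAndSummary:
    def test_fitted_model_raster_carries_provenance(self, world_cfg, world):
        samples, truth = generate_samples(world_cfg, 120, world=world)
        table = truth.covariates.copy()
        table["d2h"] = samples["d2h"].to_numpy()
        fit = fit_ols(FULL_MODEL, table)
        raster = predict_raster(fit, world.altitude, world.climate, world.regions)
        assert raster.provenance["n_fit"] == 120
        assert raster.grid.same_lattice(world.altitude)
        assert np.isfinite(raster.grid.data).all()

    def test_summary_of_constant_raster(self):
        from plumascape.isoscape import IsoscapeRaster

        r = IsoscapeRaster(Grid(np.full((2, 2), -30.0), 0, 0, 1.0))
        s = summarize(r)
        assert s["min"] == s["max"] == s["mean"] == -30.0

    def test_summary_two_values_and_mask_exclusion(self):
        from plumascape.isoscape import IsoscapeRaster

        data = np.array([[-10.0, -20.0], [np.nan, np.nan]])
        s = summarize(IsoscapeRaster(Grid(data, 0, 0, 1.0)))
        assert (s["min"], s["max"], s["mean"], s["n_cells"]) == (-20.0, -10.0, -15.0, 2)

    def test_fully_masked_raster_rejected(self):
        from plumascape.isoscape import IsoscapeRaster

        with pytest.raises(IsoscapeError):
            summarize(IsoscapeRaster(Grid(np.full((2, 2), np.nan), 0, 0, 1.0)))
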