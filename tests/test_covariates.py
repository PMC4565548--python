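"""Covariate assembly, coastline distance and the collinearity screen."""

import numpy as np
import pandas as pd
import pytest

from plumascape.covariates import (
    CovariateError,
    build_covariate_table,
    correlation_screen,
    distance_to_coast,
    region_weights_at,
    resolve_altitude,
)
from plumascape.grids import Grid, GridStack
from plumascape.synthetic import generate_samples


class TestResolveAltitude:
    def test_grid_only(self):
        assert resolve_altitude(500.0, None) == 500.0

    def test_discordant_label_wins(self):
        assert resolve_altitude(500.0, 1200.0) == 1200.0

    def test_within_threshold_keeps_grid(self):
        assert resolve_altitude(500.0, 510.0, discordance_m=100.0) == 500.0

    def test_label_only(self):
        assert resolve_altitude(None, 800.0) == 800.0

    def test_both_missing_is_an_error(self):
        with pytest.raises(CovariateError):
            resolve_altitude(None, np.nan)


class TestDistanceToCoast:
    MERIDIAN = np.array([[0.0, -10.0], [0.0, 10.0]])

    def test_point_on_the_coastline_is_zero(self):
        assert distance_to_coast(0.0, 3.0, self.MERIDIAN) == pytest.approx(0.0, abs=1e-6)

    def test_one_degree_east_at_equator(self):
        """1° of arc ≈ 111.2 km on the WGS84 mean-radius sphere."""
        d = distance_to_coast(1.0, 0.0, self.MERIDIAN)
        assert d == pytest.approx(111.195, abs=0.05)

    def test_nearer_of_two_segments(self):
        coast = np.array([[0.0, -10.0], [0.0, 10.0], [5.0, 10.0]])
        d = distance_to_coast(4.0, 0.0, coast)
        # the meridian segment at 4° beats the northern segment at 10°
        assert d == pytest.approx(4 * 111.195, rel=0.01)

    def test_beyond_segment_end_uses_endpoint(self):
        seg = np.array([[0.0, 0.0], [0.0, 5.0]])
        d = distance_to_coast(0.0, 8.0, seg)
        assert d == pytest.approx(3 * 111.195, rel=0.01)

    def test_empty_coastline_rejected(self):
        with pytest.raises(CovariateError):
            distance_to_coast(0.0, 0.0, np.empty((0, 2)))


class TestCorrelationScreen:
    def make_table(self, rng, n=200):
        t = pd.DataFrame(
            {
                "ABS_LAT": rng.uniform(0, 35, n),
                "ALT": rng.uniform(0, 3000, n),
                "PREC_TOT": rng.uniform(100, 3000, n),
                "SI": rng.uniform(0, 1.8, n),
            }
        )
        t["NDVI"] = rng.uniform(0, 1, n)
        t["ET"] = rng.uniform(0, 150, n)
        t["DIST_SEA"] = rng.uniform(0, 2000, n)
        return t

    def test_matrix_symmetric_unit_diagonal(self, rng):
        _, _, corr = correlation_screen(self.make_table(rng))
        np.testing.assert_allclose(corr.to_numpy(), corr.to_numpy().T, atol=1e-12)
        np.testing.assert_allclose(np.diag(corr.to_numpy()), 1.0)

    def test_independent_candidates_all_retained(self, rng):
        retained, excluded, _ = correlation_screen(self.make_table(rng))
        assert excluded == []
        assert set(retained) >= {"ABS_LAT", "ALT", "PREC_TOT", "SI"}

    def test_collinear_candidate_excluded(self, rng):
        t = self.make_table(rng)
        t["NDVI"] = 0.9 * t["PREC_TOT"] + rng.normal(0, 50, len(t))
        # brute-force Pearson confirms the construction is over threshold
        r = np.corrcoef(t["NDVI"], t["PREC_TOT"])[0, 1]
        assert abs(r) > 0.5
        _, excluded, _ = correlation_screen(t, threshold=0.5)
        assert "NDVI" in excluded

    def test_mutually_collinear_candidates_both_dropped(self, rng):
        t = self.make_table(rng)
        t["ET"] = 100 * t["NDVI"] + rng.normal(0, 10, len(t))
        _, excluded, _ = correlation_screen(t)
        assert {"NDVI", "ET"} <= set(excluded)

    def test_retained_core_is_never_dropped(self, rng):
        t = self.make_table(rng)
        t["DIST_SEA"] = t["ALT"] * 0.6 + rng.normal(0, 100, len(t))
        retained, excluded, _ = correlation_screen(t)
        assert "ALT" in retained and "DIST_SEA" in excluded

    def test_zero_variance_column_named(self, rng):
        t = self.make_table(rng)
        t["SI"] = 0.7
        with pytest.raises(CovariateError, match="SI"):
            correlation_screen(t)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(CovariateError):
            correlation_screen(self.make_table(rng, n=2))


class TestRegionWeights:
    def make_membership(self, weights):
        bands = [
            Grid(np.full((2, 2), w), 0.0, 2.0, 1.0) for w in weights
        ]
        return GridStack(bands, labels=[f"region_{i+1}" for i in range(len(weights))])

    def test_one_hot_returns_unit_weight(self):
        m = self.make_membership([1.0, 0.0, 0.0])
        np.testing.assert_allclose(region_weights_at(m, 0.5, 1.5), [1, 0, 0])

    def test_valid_simplex_unchanged(self):
        m = self.make_membership([0.5, 0.5, 0.0, 0.0, 0.0, 0.0])
        np.testing.assert_allclose(
            region_weights_at(m, 0.5, 1.5), [0.5, 0.5, 0, 0, 0, 0]
        )

    def test_nodata_band_renormalized(self):
        m = self.make_membership([0.5, 0.25, np.nan])
        w = region_weights_at(m, 0.5, 1.5)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(w, [2 / 3, 1 / 3, 0.0])

    def test_all_nodata_is_an_error(self):
        m = self.make_membership([np.nan, np.nan])
        with pytest.raises(CovariateError):
            region_weights_at(m, 0.5, 1.5)


class TestBuildCovariateTable:
    def test_extractions_equal_generator_truth(self, world_cfg, world):
        """Covariates re-extracted from the grids match the generator exactly."""
        samples, truth = generate_samples(world_cfg, 60, world=world)
        cov = build_covariate_table(
            samples,
            altitude=world.altitude,
            climate=world.climate,
            membership=world.regions,
        )
        for col in ("ABS_LAT", "ALT", "PREC_TOT", "SI", *(f"w_{r}" for r in range(1, 7))):
            np.testing.assert_allclose(
                cov[col].to_numpy(), truth.covariates[col].to_numpy(), atol=1e-12,
                err_msg=col,
            )

    def test_phenology_and_coast_columns_present(self, world_cfg, world):
        samples, _ = generate_samples(world_cfg, 10, world=world)
        coast = np.array([[world_cfg.lon_min, world_cfg.lat_min],
                          [world_cfg.lon_min, world_cfg.lat_max]])
        cov = build_covariate_table(
            samples, world.altitude, world.climate, world.regions,
            d2h_precip=world.d2h, coastline=coast,
        )
        for col in ("moult_month", "d2h_precip_annual", "d2h_precip_moult_month",
                    "d2h_precip_moult_season", "DIST_SEA"):
            assert col in cov.columns and cov[col].notna().all()
        assert (cov["DIST_SEA"] >= 0).all()
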