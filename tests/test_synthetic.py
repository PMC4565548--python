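"""The synthetic world: determinism, construction invariants, ground truth."""

import numpy as np
import pandas as pd
import pytest

from plumascape.modeling import FULL_MODEL, design_matrix
from plumascape.synthetic import (
    TrueCoefficients,
    WorldConfig,
    generate_climate,
    generate_regions,
    generate_samples,
    generate_specimen_table,
    generate_standard_runs,
    generate_world,
)


class TestConfigValidation:
    def test_degenerate_extent_rejected(self):
        with pytest.raises(ValueError, match="extent"):
            WorldConfig(lon_min=10.0, lon_max=10.0)

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValueError, match="regions"):
            WorldConfig(n_regions=1, coefficients=TrueCoefficients(region=()))

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            WorldConfig(sigma=-1.0)


class TestClimate:
    def test_same_seed_bit_identical(self):
        cfg = WorldConfig(seed=11)
        a = generate_climate(cfg).as_array()
        b = generate_climate(cfg).as_array()
        np.testing.assert_array_equal(a, b)

    def test_zero_seasonality_gives_uniform_months(self):
        cfg = WorldConfig(seed=11, strength_range=(0.0, 0.0))
        months = generate_climate(cfg).as_array()
        np.testing.assert_allclose(
            months, np.broadcast_to(months[0], months.shape), rtol=1e-12
        )

    def test_peak_month_is_argmax_everywhere(self, world, world_cfg):
        months = world.climate.as_array()
        argmax = months.argmax(axis=0) + 1
        np.testing.assert_array_equal(argmax, world.peak.data.astype(int))

    def test_annual_total_matches_configured_field(self, world):
        total = world.climate.as_array().sum(axis=0)
        np.testing.assert_allclose(total, world.annual_total.data, rtol=1e-9)

    def test_precipitation_non_negative(self, world):
        assert (world.climate.as_array() >= 0).all()

    def test_full_strength_puts_all_rain_in_peak_month(self):
        cfg = WorldConfig(seed=5, strength_range=(1.0, 1.0))
        months = generate_climate(cfg).as_array()
        nonzero_months = (months > 1e-12).sum(axis=0)
        np.testing.assert_array_equal(nonzero_months, 1)


class TestRegions:
    def test_simplex_constraint_everywhere(self, world):
        sums = world.regions.as_array().sum(axis=0)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
        assert (world.regions.as_array() >= 0).all()

    def test_one_hot_mode_is_exactly_degenerate(self):
        cfg = WorldConfig(seed=9)
        stack, _ = generate_regions(cfg, one_hot=True)
        arr = stack.as_array()
        assert set(np.unique(arr)) <= {0.0, 1.0}
        np.testing.assert_array_equal(arr.sum(axis=0), 1.0)

    def test_each_region_dominates_its_own_center(self):
        cfg = WorldConfig(seed=9)
        stack, centers = generate_regions(cfg)
        for r, (lon, lat) in enumerate(centers):
            w = stack.extract_at(lon, lat)
            assert np.argmax(w) == r

    def test_weights_spatially_smooth(self, world):
        """Fuzzy membership changes by less than 0.15 between neighbours."""
        arr = world.regions.as_array()
        assert np.abs(np.diff(arr, axis=1)).max() < 0.15
        assert np.abs(np.diff(arr, axis=2)).max() < 0.15


class TestSamples:
    def test_zero_noise_observed_equals_linear_predictor(self):
        cfg = WorldConfig(seed=2, sigma=0.0)
        samples, truth = generate_samples(cfg, 50)
        np.testing.assert_allclose(samples["d2h"].to_numpy(), truth.noiseless, rtol=0, atol=1e-12)

    def test_intercept_only_world_is_constant(self):
        coef = TrueCoefficients(
            intercept=-33.0, abs_lat=0, abs_lat2=0, alt=0, prec_tot=0, si=0,
            region=(0.0,) * 5,
        )
        cfg = WorldConfig(seed=2, sigma=0.0, coefficients=coef)
        samples, _ = generate_samples(cfg, 20)
        np.testing.assert_allclose(samples["d2h"], -33.0, atol=1e-12)

    def test_prec_tot_coefficient_arithmetic(self):
        """−0.008978 ‰ per mm: 1000 mm more annual rain → −8.978 ‰."""
        coef = TrueCoefficients(
            intercept=0, abs_lat=0, abs_lat2=0, alt=0, prec_tot=-0.008978, si=0,
            region=(0.0,) * 5,
        )
        table = pd.DataFrame(
            {"ABS_LAT": [0.0, 0.0], "ALT": [0.0, 0.0], "PREC_TOT": [500.0, 1500.0],
             "SI": [0.0, 0.0], **{f"w_{r}": [0.0, 0.0] for r in range(2, 7)}}
        )
        pred = coef.linear_predictor(table)
        assert pred[1] - pred[0] == pytest.approx(-8.978, abs=1e-12)

    def test_sample_coordinates_inside_extent(self, world_cfg, world):
        samples, _ = generate_samples(world_cfg, 100, world=world)
        assert samples["lon"].between(world_cfg.lon_min, world_cfg.lon_max).all()
        assert samples["lat"].between(world_cfg.lat_min, world_cfg.lat_max).all()

    def test_at_least_one_sample_required(self, world_cfg, world):
        with pytest.raises(ValueError):
            generate_samples(world_cfg, 0, world=world)

    def test_noise_streams_give_independent_replicates(self, world_cfg, world):
        a, _ = generate_samples(world_cfg, 30, world=world, noise_stream=1)
        b, _ = generate_samples(world_cfg, 30, world=world, noise_stream=2)
        assert not np.allclose(a["d2h"], b["d2h"])

    def test_truth_reproduced_by_design_matrix_at_true_coefficients(self):
        """The modeling stage's design times the true β equals the noiseless values."""
        cfg = WorldConfig(seed=4, sigma=0.0)
        samples, truth = generate_samples(cfg, 80)
        X = design_matrix(FULL_MODEL, truth.covariates)
        c = cfg.coefficients
        beta = np.array(
            [c.intercept, c.abs_lat, c.abs_lat2, c.alt, c.prec_tot, c.si, *c.region]
        )
        assert list(X.columns) == ["const", "ABS_LAT", "ABS_LAT2", "ALT", "PREC_TOT", "SI",
                                   "w_2", "w_3", "w_4", "w_5", "w_6"]
        np.testing.assert_allclose(X.to_numpy() @ beta, truth.noiseless, atol=1e-10)


class TestSpecimenTable:
    def test_museum_structure_counts(self, world_cfg, world):
        table, _ = generate_specimen_table(world_cfg, world=world)
        assert len(table) == 224
        assert table["locality"].nunique() == 205
        assert table["country"].nunique() == 34
        assert table["collection_year"].between(1950, 2014).all()

    def test_same_seed_identical_table(self, world_cfg, world):
        a, _ = generate_specimen_table(world_cfg, world=world)
        b, _ = generate_specimen_table(world_cfg, world=world)
        pd.testing.assert_frame_equal(a, b)

    def test_structure_arguments_validated(self, world_cfg, world):
        with pytest.raises(ValueError):
            generate_specimen_table(world_cfg, n_specimens=10, n_localities=20, world=world)

    def test_standard_runs_recover_instrument_map(self, world_cfg):
        from plumascape.calibration import fit_calibration
        from plumascape.synthetic import INSTRUMENT_INTERCEPT, INSTRUMENT_SLOPE

        cal = fit_calibration(generate_standard_runs(world_cfg, n_replicates=30))
        assert cal.slope == pytest.approx(INSTRUMENT_SLOPE, rel=0.05)
        assert cal.intercept == pytest.approx(INSTRUMENT_INTERCEPT, abs=2.0)


def test_world_determinism_across_full_bundle():
    cfg = WorldConfig(seed=13)
    w1, w2 = generate_world(cfg), generate_world(cfg)
    np.testing.assert_array_equal(w1.altitude.data, w2.altitude.data)
    np.testing.assert_array_equal(w1.d2h.as_array(), w2.d2h.as_array())
    np.testing.assert_array_equal(w1.regions.as_array(), w2.regions.as_array())
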