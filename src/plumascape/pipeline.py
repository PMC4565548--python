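"""End-to-end pipeline runner over the synthetic world.

Chains the stages synthesize → calibrate → phenology/covariates →
screen → fit/select → predict → compare into one reproducible run:
a TOML (or keyword) configuration, one seed, a run directory with the
stage artifacts and a JSON manifest recording configuration, seed,
selected model and output hashes.  Every stage output is a pure
function of (config, seed); running the same configuration twice
yields identical manifests apart from the timestamp.

Real-data use bypasses this runner: the stage modules accept any
user-supplied sample CSV and raster stacks directly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import comparison, covariates, isoscape, modeling, synthetic
from .calibration import apply_calibration, fit_calibration
from .grids import write_ascii_grid, write_stack

__all__ = ["PipelineConfig", "PipelineError", "run"]

log = logging.getLogger("plumascape")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Run configuration; every documented methodological default is a key."""

    out_dir: str = "runs/latest"
    seed: int = 0
    sigma: float = 3.0
    n_specimens: int = synthetic.DEFAULT_N_SPECIMENS
    n_localities: int = synthetic.DEFAULT_N_LOCALITIES
    n_countries: int = synthetic.DEFAULT_N_COUNTRIES
    cell: float = 1.0
    screen_threshold: float = 0.5
    alt_discordance_m: float = 100.0
    ci_level: float = 0.95
    resample_cell: float = 3.0  # coarse lattice for isoscape comparison, degrees
    sd_population: bool = False  # |a-b|/2 instead of |a-b|/sqrt(2)
    write_rasters: bool = True

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.seed < 0:
            raise PipelineError("seed must be non-negative")
        if not 0 < self.ci_level < 1:
            raise PipelineError("ci_level must be in (0, 1)")
        if self.resample_cell < self.cell:
            raise PipelineError("resample_cell must be at least the native cell size")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "seed": config.seed,
        "stages": {},
        "started": datetime.now(timezone.utc).isoformat(),
    }

    def fail(stage: str, exc: Exception) -> None:
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- synthesize -------------------------------------------------
    try:
        world_cfg = synthetic.WorldConfig(seed=config.seed, sigma=config.sigma, cell=config.cell)
        world = synthetic.generate_world(world_cfg)
        table, truth = synthetic.generate_specimen_table(
            world_cfg,
            n_specimens=config.n_specimens,
            n_localities=config.n_localities,
            n_countries=config.n_countries,
            world=world,
        )
        standards = synthetic.generate_standard_runs(world_cfg)
        table.to_csv(out / "specimens.csv", index=False)
        if config.write_rasters:
            write_ascii_grid(world.altitude, out / "altitude.asc")
            write_stack(world.climate, out / "climate", prefix="prec")
            write_stack(world.d2h, out / "d2h_precip", prefix="d2h")
            write_stack(world.regions, out / "regions", prefix="memb")
        log.info("synthesize: n=%d specimens on %s grid", len(table), world_cfg.shape)
        manifest["stages"]["synthesize"] = {
            "status": "ok",
            "n_specimens": int(len(table)),
            "n_localities": int(table["locality"].nunique()),
            "n_countries": int(table["country"].nunique()),
        }
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        fail("synthesize", exc)

    # --- calibrate --------------------------------------------------
    try:
        cal = fit_calibration(standards)
        table["d2h"] = apply_calibration(cal, table["d2h_raw"].to_numpy())
        table.to_csv(out / "specimens_calibrated.csv", index=False)
        log.info(
            "calibrate: slope=%.4f intercept=%.2f qc_flag=%s",
            cal.slope, cal.intercept, cal.qc_flag,
        )
        manifest["stages"]["calibrate"] = {
            "status": "ok",
            "slope": cal.slope,
            "intercept": cal.intercept,
            "residuals": cal.residuals,
            "qc_flag": cal.qc_flag,
        }
    except Exception as exc:  # noqa: BLE001
        fail("calibrate", exc)

    # --- covariates (incl. phenology joins and screen) --------------
    try:
        coast = np.array(
            [[world_cfg.lon_min, world_cfg.lat_min], [world_cfg.lon_min, world_cfg.lat_max]]
        )  # synthetic convention: the western grid edge is the coast
        cov = covariates.build_covariate_table(
            table,
            altitude=world.altitude,
            climate=world.climate,
            membership=world.regions,
            d2h_precip=world.d2h,
            coastline=coast,
            discordance_m=config.alt_discordance_m,
        )
        cov.to_csv(out / "covariates.csv", index=False)
        retained, excluded, corr = covariates.correlation_screen(
            cov, threshold=config.screen_threshold
        )
        corr.to_csv(out / "correlation_matrix.csv")
        log.info("covariates: n=%d retained=%s excluded=%s", len(cov), retained, excluded)
        manifest["stages"]["covariates"] = {
            "status": "ok",
            "n": int(len(cov)),
            "retained": retained,
            "excluded": excluded,
        }
    except Exception as exc:  # noqa: BLE001
        fail("covariates", exc)

    # --- fit & select -----------------------------------------------
    try:
        fits = [
            modeling.fit_ols(spec, cov, ci_level=config.ci_level)
            for spec in modeling.enumerate_candidates(world_cfg.n_regions)
        ]
        ranked = modeling.rank_models(fits)
        importance = modeling.relative_importance(ranked)
        best = ranked[0]
        ranking = pd.DataFrame(
            {
                "model": [f.spec.label() for f in ranked],
                "k": [f.k for f in ranked],
                "aicc": [f.aicc for f in ranked],
                "delta_aicc": [f.delta_aicc for f in ranked],
                "weight": [f.weight for f in ranked],
                "r_squared": [f.r_squared for f in ranked],
            }
        )
        ranking.to_csv(out / "model_ranking.csv", index=False)
        coef = pd.DataFrame(
            {
                "estimate": best.params,
                "std_error": best.bse,
                "t_value": best.tvalues,
                "p_value": best.pvalues,
                "ci_lower": best.conf_int["lower"],
                "ci_upper": best.conf_int["upper"],
            }
        )
        coef.to_csv(out / "selected_model_coefficients.csv")
        log.info(
            "fit: selected '%s' weight=%.3f R2=%.3f F%s=%.2f",
            best.spec.label(), best.weight, best.r_squared, best.f_df, best.f_statistic,
        )
        manifest["stages"]["fit"] = {
            "status": "ok",
            "n_candidates": len(fits),
            "selected": best.spec.label(),
            "weight": best.weight,
            "r_squared": best.r_squared,
            "f": {"statistic": best.f_statistic, "df": list(best.f_df)},
            "supported_set": [f.spec.label() for f in modeling.supported_set(ranked)],
            "importance": importance,
        }
    except Exception as exc:  # noqa: BLE001
        fail("fit", exc)

    # --- predict ----------------------------------------------------
    try:
        raster = isoscape.predict_raster(best, world.altitude, world.climate, world.regions)
        summary = isoscape.summarize(raster)
        if config.write_rasters:
            write_ascii_grid(raster.grid, out / "isoscape.asc")
        (out / "isoscape_summary.json").write_text(
            json.dumps({"provenance": raster.provenance, "summary": summary}, indent=1)
        )
        log.info("predict: range %.1f to %.1f permil", summary["min"], summary["max"])
        manifest["stages"]["predict"] = {"status": "ok", **{
            k: summary[k] for k in ("min", "max", "mean", "n_cells")
        }}
    except Exception as exc:  # noqa: BLE001
        fail("predict", exc)

    # --- compare against a prior isoscape ---------------------------
    try:
        truth_surface = isoscape.predict_surface(
            _truth_coeff_mapping(world_cfg), world.altitude, world.climate, world.regions
        )
        prior = synthetic.make_prior_isoscape(world_cfg, truth_surface)
        ours_coarse = comparison.resample(raster.grid, config.resample_cell)
        prior_coarse = comparison.resample(prior, config.resample_cell)
        mismatch = comparison.sd_map(ours_coarse, prior_coarse, population=config.sd_population)
        report = comparison.regress_observed(table, prior)
        if config.write_rasters:
            write_ascii_grid(mismatch, out / "sd_map.asc")
            write_ascii_grid(prior, out / "prior_isoscape.asc")
        log.info("compare: regression R2=%.3f on n=%d", report.r_squared, report.n)
        manifest["stages"]["compare"] = {
            "status": "ok",
            "regression": {
                "slope": report.slope,
                "intercept": report.intercept,
                "r_squared": report.r_squared,
                "f_statistic": report.f_statistic,
                "f_df": list(report.f_df),
                "p_value": report.p_value,
                "n": report.n,
            },
            "sd_map_mean": float(np.nanmean(mismatch.data)),
        }
    except Exception as exc:  # noqa: BLE001
        fail("compare", exc)

    manifest["finished"] = datetime.now(timezone.utc).isoformat()
    manifest["artifact_hashes"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*.csv")) + sorted(out.glob("*.json"))
        if p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _truth_coeff_mapping(cfg: synthetic.WorldConfig) -> dict[str, float]:
    c = cfg.coefficients
    out = {
        "const": c.intercept,
        "ABS_LAT": c.abs_lat,
        "ABS_LAT2": c.abs_lat2,
        "ALT": c.alt,
        "PREC_TOT": c.prec_tot,
        "SI": c.si,
    }
    for r, beta in enumerate(c.region, start=2):
        out[f"w_{r}"] = beta
    return out
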