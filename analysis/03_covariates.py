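"""Assemble per-specimen covariates and run the collinearity screen.

Joins the calibrated specimen table with the world rasters: absolute
latitude, altitude (grid vs. label), annual precipitation, Walsh–Lawler
seasonality, distance to the (synthetic, western-edge) coast, fuzzy
region weights, and the amount-weighted precipitation-δ²H summaries for
the annual, moult-month and moult-season windows.  Then screens the
continuous covariates with a Pearson correlation matrix.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from plumascape.covariates import build_covariate_table, correlation_screen
from plumascape.synthetic import WorldConfig, generate_world

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--screen-threshold", type=float, default=0.5)
    args = parser.parse_args()
    results = ROOT / "results"

    wc = json.loads((results / "world_config.json").read_text())
    cfg = WorldConfig(seed=wc["seed"], sigma=wc["sigma"], cell=wc["cell"])
    world = generate_world(cfg)
    table = pd.read_csv(results / "specimens_calibrated.csv")

    coast = np.array([[cfg.lon_min, cfg.lat_min], [cfg.lon_min, cfg.lat_max]])
    cov = build_covariate_table(
        table,
        altitude=world.altitude,
        climate=world.climate,
        membership=world.regions,
        d2h_precip=world.d2h,
        coastline=coast,
    )
    cov.to_csv(results / "covariates.csv", index=False, float_format="%.6g")

    retained, excluded, corr = correlation_screen(cov, threshold=args.screen_threshold)
    corr.to_csv(results / "correlation_matrix.csv", float_format="%.4f")

    print(f"covariates for {len(cov)} specimens")
    print(f"SI range {cov['SI'].min():.2f}-{cov['SI'].max():.2f}, "
          f"PREC_TOT {cov['PREC_TOT'].min():.0f}-{cov['PREC_TOT'].max():.0f} mm")
    print(f"screen at |r| > {args.screen_threshold}: retained {retained}; excluded {excluded}")
    print("correlation matrix -> results/correlation_matrix.csv")


if __name__ == "__main__":
    main()
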