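"""Calibrate raw specimen δ²H to the VSMOW scale.

Fits the comparative-equilibration line from the replicate keratin-
standard runs (CBS, KHS, LIE-PA2) written by 01_build_world.py and
applies it to every specimen's raw value, reporting per-standard
residuals and the ±3‰ QC flag.
"""

import argparse
from pathlib import Path

import pandas as pd

from plumascape.calibration import KeratinStandard, apply_calibration, fit_calibration

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.parse_args()
    results = ROOT / "results"

    std = pd.read_csv(results / "standards.csv")
    rep_cols = [c for c in std.columns if c.startswith("rep_")]
    standards = [
        KeratinStandard(r["name"], r["accepted"], tuple(r[c] for c in rep_cols))
        for _, r in std.iterrows()
    ]
    cal = fit_calibration(standards)

    table = pd.read_csv(results / "specimens.csv")
    table["d2h"] = apply_calibration(cal, table["d2h_raw"].to_numpy())
    table.to_csv(results / "specimens_calibrated.csv", index=False, float_format="%.6g")

    print(f"calibration: VSMOW = {cal.slope:.4f} * raw + {cal.intercept:.2f}")
    for name, resid in cal.residuals.items():
        print(f"  {name:8s} residual {resid:+.2f} permil")
    print(f"QC flag (any residual beyond 3 permil): {cal.qc_flag}")
    print(
        f"calibrated {len(table)} specimens: "
        f"{table['d2h'].min():.1f} to {table['d2h'].max():.1f} permil"
    )


if __name__ == "__main__":
    main()
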