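"""Comparative-equilibration calibration of feather δ²H to the VSMOW scale.

Non-exchangeable hydrogen in keratin is measured against keratin
reference materials equilibrated with the same ambient water vapour as
the unknowns, so that exchangeable-H effects cancel.  The calibration is
an affine map fitted by ordinary least squares from the mean measured
value of each standard to its accepted value.

Default standards (accepted δ²H, ‰ VSMOW):

* CBS, caribou hoof: −197
* KHS, kudu horn: −54.1
* LIE-PA2, razorbill feathers: +20.8

A run is flagged for QC when any standard's residual exceeds the
nominal ±3‰ within-run measurement error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KeratinStandard",
    "CalibrationMap",
    "CalibrationError",
    "DEFAULT_STANDARDS",
    "fit_calibration",
    "apply_calibration",
]

QC_RESIDUAL_LIMIT = 3.0  # ‰, the nominal within-run measurement error


class CalibrationError(ValueError):
    pass


@dataclass
class KeratinStandard:
    """A keratin reference material with replicate within-run measurements."""

    name: str
    accepted: float  # ‰ VSMOW
    measured: tuple[float, ...]  # raw instrument units, >= 1 replicate

    def __post_init__(self) -> None:
        self.measured = tuple(float(m) for m in self.measured)
        if len(self.measured) < 1:
            raise CalibrationError(f"standard {self.name}: at least one replicate required")

    @property
    def mean_measured(self) -> float:
        return float(np.mean(self.measured))


DEFAULT_ACCEPTED = {"CBS": -197.0, "KHS": -54.1, "LIE-PA2": 20.8}
DEFAULT_STANDARDS = tuple(DEFAULT_ACCEPTED.items())


@dataclass
class CalibrationMap:
    """Affine raw→VSMOW map with per-standard residuals for QC."""

    slope: float
    intercept: float
    residuals: dict[str, float]

    @property
    def qc_flag(self) -> bool:
        """True when any standard residual exceeds the ±3‰ run error."""
        return any(abs(r) > QC_RESIDUAL_LIMIT for r in self.residuals.values())

    def __call__(self, raw):
        return apply_calibration(self, raw)


def fit_calibration(standards: list[KeratinStandard]) -> CalibrationMap:
    """Least-squares line mapping mean measured values to accepted values.

    With two standards the line is exact; with three or more it
    minimises squared error and the residuals expose run quality.
    """
    if len(standards) < 2:
        raise CalibrationError("at least two standards required")
    accepted = np.array([s.accepted for s in standards])
    measured = np.array([s.mean_measured for s in standards])
    if np.ptp(accepted) == 0:
        raise CalibrationError("degenerate calibration: all accepted values equal")
    if np.ptp(measured) == 0:
        raise CalibrationError("degenerate calibration: all measured means equal")
    slope, intercept = np.polyfit(measured, accepted, 1)
    fitted = slope * measured + intercept
    residuals = {s.name: float(a - f) for s, a, f in zip(standards, accepted, fitted)}
    return CalibrationMap(float(slope), float(intercept), residuals)


def apply_calibration(cal: CalibrationMap, raw):
    """Apply the affine map elementwise; NaN (nodata) propagates."""
    raw_arr = np.asarray(raw, dtype=float)
    out = cal.slope * raw_arr + cal.intercept
    if np.isscalar(raw) or raw_arr.ndim == 0:
        return float(out)
    return out
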