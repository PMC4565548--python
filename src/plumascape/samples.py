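"""Specimen sample tables: schema, validation and CSV interchange.

A sample record describes one feather specimen: a georeferenced
collection locality, optional label metadata (altitude, country,
collection year) and the δ²H response — raw instrument units
(``d2h_raw``) and/or calibrated ‰ VSMOW (``d2h``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["SampleRecord", "SampleFormatError", "read_samples", "write_samples", "samples_to_frame"]

# Plausibility window for feather δ²H on the VSMOW scale (‰).
D2H_MIN, D2H_MAX = -400.0, 100.0

REQUIRED_COLUMNS = ("id", "lon", "lat")
OPTIONAL_COLUMNS = ("alt_label", "d2h_raw", "d2h", "country", "collection_year", "locality")


class SampleFormatError(ValueError):
    """The sample table violated the expected schema or an invariant."""


@dataclass
class SampleRecord:
    id: str
    lon: float
    lat: float
    alt_label: float | None = None
    d2h_raw: float | None = None
    d2h: float | None = None
    country: str | None = None
    collection_year: int | None = None
    locality: str | None = None

    def __post_init__(self) -> None:
        if not -180.0 <= self.lon <= 180.0:
            raise SampleFormatError(f"sample {self.id}: longitude {self.lon} outside [-180, 180]")
        if not -90.0 <= self.lat <= 90.0:
            raise SampleFormatError(f"sample {self.id}: latitude {self.lat} outside [-90, 90]")
        if self.d2h is not None and not D2H_MIN <= self.d2h <= D2H_MAX:
            raise SampleFormatError(
                f"sample {self.id}: δ²H {self.d2h}‰ outside sanity window "
                f"[{D2H_MIN}, {D2H_MAX}]"
            )


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return str(value)


def read_samples(path: str | Path) -> list[SampleRecord]:
    """Read a specimen CSV into validated records.

    Requires ``id``, ``lon``, ``lat`` and at least one of ``d2h`` /
    ``d2h_raw``; missing optional fields are preserved as absent.
    """
    df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SampleFormatError(f"missing required column {col!r} in {path}")
    if "d2h" not in df.columns and "d2h_raw" not in df.columns:
        raise SampleFormatError(f"missing δ²H column ('d2h' or 'd2h_raw') in {path}")
    records = []
    for row in df.to_dict("records"):
        year = _opt_float(row.get("collection_year"))
        records.append(
            SampleRecord(
                id=str(row["id"]),
                lon=float(row["lon"]),
                lat=float(row["lat"]),
                alt_label=_opt_float(row.get("alt_label")),
                d2h_raw=_opt_float(row.get("d2h_raw")),
                d2h=_opt_float(row.get("d2h")),
                country=_opt_str(row.get("country")),
                collection_year=None if year is None else int(year),
                locality=_opt_str(row.get("locality")),
            )
        )
    return records


def samples_to_frame(records: list[SampleRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "lon": r.lon,
                "lat": r.lat,
                "alt_label": r.alt_label,
                "d2h_raw": r.d2h_raw,
                "d2h": r.d2h,
                "country": r.country,
                "collection_year": r.collection_year,
                "locality": r.locality,
            }
        )
    return pd.DataFrame(rows)


def write_samples(records: list[SampleRecord], path: str | Path) -> None:
    samples_to_frame(records).to_csv(path, index=False)
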