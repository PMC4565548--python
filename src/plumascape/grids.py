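"""Georeferenced raster grids and plain-text raster I/O.

All grids in the pipeline live on a WGS84 lon/lat lattice, north-up
(row 0 is the northernmost row), with square cells and cell-center
registration for point lookups.  Rasters are stored as ESRI ASCII grid
files (``.asc``), a plain-text format understood by every GIS; 12-month
precipitation stacks and 6-region membership stacks are directories of
per-band ``.asc`` files plus a small JSON band manifest.

Nodata is represented internally as NaN and flagged explicitly on disk
(``NODATA_value``); a nodata cell is never silently numeric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Grid",
    "GridStack",
    "OutOfExtentError",
    "GridFormatError",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_stack",
    "write_stack",
]

NODATA = -9999.0


class OutOfExtentError(ValueError):
    """A point lookup fell outside the grid's extent."""


class GridFormatError(ValueError):
    """A raster file violated the expected on-disk format."""


@dataclass
class Grid:
    """A single-band raster on a regular WGS84 lon/lat lattice.

    Parameters
    ----------
    data : ndarray of shape (nrows, ncols)
        Cell values, north-up; nodata cells are NaN.
    west : float
        Longitude of the western edge of the grid (left edge of column 0).
    north : float
        Latitude of the northern edge of the grid (top edge of row 0).
    cell : float
        Cell size in decimal degrees (square cells).
    """

    data: np.ndarray
    west: float
    north: float
    cell: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise GridFormatError("grid data must be 2-D")
        if not self.cell > 0:
            raise GridFormatError("cell size must be positive")

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def south(self) -> float:
        return self.north - self.nrows * self.cell

    @property
    def east(self) -> float:
        return self.west + self.ncols * self.cell

    def lon_centers(self) -> np.ndarray:
        return self.west + (np.arange(self.ncols) + 0.5) * self.cell

    def lat_centers(self) -> np.ndarray:
        return self.north - (np.arange(self.nrows) + 0.5) * self.cell

    def same_lattice(self, other: "Grid") -> bool:
        """True when both grids share shape, origin and cell size exactly."""
        return (
            self.data.shape == other.data.shape
            and self.west == other.west
            and self.north == other.north
            and self.cell == other.cell
        )

    def index_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Row/column of the cell whose center is nearest the point.

        Raises :class:`OutOfExtentError` when the point lies outside the
        grid's bounding box (edges inclusive).
        """
        if not (self.west <= lon <= self.east) or not (self.south <= lat <= self.north):
            raise OutOfExtentError(
                f"point ({lon}, {lat}) outside extent "
                f"[{self.west}, {self.east}] x [{self.south}, {self.north}]"
            )
        col = int(np.clip(np.floor((lon - self.west) / self.cell), 0, self.ncols - 1))
        row = int(np.clip(np.floor((self.north - lat) / self.cell), 0, self.nrows - 1))
        return row, col

    def extract_at(self, lon: float, lat: float) -> float:
        """Nearest-cell value at a point; NaN when the cell is nodata.

        No interpolation is performed: locality accuracy in museum data
        (< 10 km) does not support sub-cell precision.
        """
        row, col = self.index_of(lon, lat)
        return float(self.data[row, col])

    def copy_with(self, data: np.ndarray) -> "Grid":
        return Grid(np.asarray(data, dtype=float), self.west, self.north, self.cell)


@dataclass
class GridStack:
    """An ordered set of co-registered single-band grids.

    Used for the 12-month precipitation and precipitation-δ²H stacks
    (bands ``month_01`` .. ``month_12``) and the 6-region fuzzy
    membership stack (bands ``region_1`` .. ``region_6``).
    """

    bands: list[Grid]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.bands:
            raise GridFormatError("stack must contain at least one band")
        first = self.bands[0]
        for g in self.bands[1:]:
            if not first.same_lattice(g):
                raise GridFormatError("stack bands are not co-registered")
        if not self.labels:
            self.labels = [f"band_{i + 1:02d}" for i in range(len(self.bands))]
        if len(self.labels) != len(self.bands):
            raise GridFormatError("one label per band required")

    def __len__(self) -> int:
        return len(self.bands)

    @property
    def grid(self) -> Grid:
        """Reference grid defining the shared lattice."""
        return self.bands[0]

    def as_array(self) -> np.ndarray:
        """Bands stacked along axis 0, shape (nbands, nrows, ncols)."""
        return np.stack([g.data for g in self.bands], axis=0)

    def extract_at(self, lon: float, lat: float) -> np.ndarray:
        row, col = self.grid.index_of(lon, lat)
        return np.array([g.data[row, col] for g in self.bands])


def write_ascii_grid(grid: Grid, path: str | Path, nodata: float = NODATA) -> None:
    """Write a grid as an ESRI ASCII raster (corner-registered header)."""
    path = Path(path)
    body = np.where(np.isnan(grid.data), nodata, grid.data)
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.west!r}\n"
        f"yllcorner {grid.south!r}\n"
        f"cellsize {grid.cell!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> Grid:
    """Read an ESRI ASCII raster, mapping its nodata value to NaN."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2:
                raise GridFormatError(f"malformed header line in {path}: {line!r}")
            header[parts[0].lower()] = float(parts[1])
        data = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise GridFormatError(f"missing header field {key!r} in {path}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if data.shape != (nrows, ncols):
        raise GridFormatError(
            f"{path}: body shape {data.shape} does not match header ({nrows}, {ncols})"
        )
    nodata = header.get("nodata_value", NODATA)
    data = np.where(data == nodata, np.nan, data)
    cell = header["cellsize"]
    north = header["yllcorner"] + nrows * cell
    return Grid(data, west=header["xllcorner"], north=north, cell=cell)


def write_stack(stack: GridStack, directory: str | Path, prefix: str = "band") -> None:
    """Write a stack as one ``.asc`` per band plus a band manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for label, grid in zip(stack.labels, stack.bands):
        fname = f"{prefix}_{label}.asc"
        write_ascii_grid(grid, directory / fname)
        files.append({"label": label, "file": fname})
    (directory / f"{prefix}_bands.json").write_text(json.dumps(files, indent=1))


def read_stack(directory: str | Path, prefix: str = "band") -> GridStack:
    directory = Path(directory)
    manifest = directory / f"{prefix}_bands.json"
    if not manifest.exists():
        raise GridFormatError(f"missing band manifest {manifest}")
    entries = json.loads(manifest.read_text())
    bands = [read_ascii_grid(directory / e["file"]) for e in entries]
    return GridStack(bands, labels=[e["label"] for e in entries])
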