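"""Land-use grids and driver stacks.

The spatial unit of the whole package is a categorical raster of six land
classes (plowland, forestland, grassland, water, construction, unused),
stored as integer codes 1..6 with 0 as nodata.  Grids carry the per-cell
area in hectares and the linear cell size in metres, which is all the
georeferencing the valuation and simulation stages need.

File I/O uses the ESRI ASCII grid format (plain text), which round-trips
the array and the cell size; driver stacks are written as one ``.asc`` per
band next to a ``<stem>.bands.txt`` listing the band names.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Canonical class order used everywhere (codes 1..6 in this order).
CLASS_NAMES: tuple[str, ...] = (
    "plowland",
    "forestland",
    "grassland",
    "water",
    "construction",
    "unused",
)
N_CLASSES = len(CLASS_NAMES)
NODATA = 0


class GridAlignmentError(ValueError):
    """Two grids that must be co-registered are not."""


@dataclass(frozen=True)
class LandUseGrid:
    """Categorical land-use raster.

    Parameters
    ----------
    data
        2-D integer array of class codes 1..6; ``NODATA`` (0) marks cells
        outside the study area.
    cell_area
        Area of one cell in hectares.
    cell_size
        Linear cell size in metres.  Defaults to the size implied by
        ``cell_area`` (1 ha -> 100 m).
    """

    data: np.ndarray
    cell_area: float = 1.0
    cell_size: float = field(default=0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 2:
            raise ValueError("land-use grid must be 2-D")
        if arr.dtype.kind not in "iu":
            raise ValueError("land-use grid must hold integer class codes")
        valid = (arr == NODATA) | ((arr >= 1) & (arr <= N_CLASSES))
        if not valid.all():
            bad = np.unique(arr[~valid])
            raise ValueError(f"unknown class codes in grid: {bad.tolist()}")
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")
        object.__setattr__(self, "data", arr)
        if self.cell_size <= 0:
            object.__setattr__(self, "cell_size", float(np.sqrt(self.cell_area * 1e4)))

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return self.data != NODATA

    def class_counts(self) -> np.ndarray:
        """Cell counts per class, in canonical class order."""
        return np.bincount(self.data.ravel(), minlength=N_CLASSES + 1)[1:]

    def require_aligned(self, other: "LandUseGrid") -> None:
        if self.shape != other.shape:
            raise GridAlignmentError(
                f"grid shapes differ: {self.shape} vs {other.shape}"
            )
        if not np.isclose(self.cell_area, other.cell_area):
            raise GridAlignmentError("grid cell areas differ")
        if not np.array_equal(self.valid_mask, other.valid_mask):
            raise GridAlignmentError("grid nodata masks differ")


@dataclass(frozen=True)
class DriverStack:
    """Stack of continuous driver rasters scaled to [0, 1].

    Drivers play the role of the suitability covariates (elevation, GDP,
    population density, distances, NDVI, ...) in the logistic regression
    stage; they must be co-registered with the land-use grid.
    """

    names: tuple[str, ...]
    data: np.ndarray  # (n_drivers, rows, cols)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 3:
            raise ValueError("driver stack must be (bands, rows, cols)")
        if arr.shape[0] != len(self.names):
            raise ValueError("driver names do not match band count")
        object.__setattr__(self, "data", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def as_table(self) -> np.ndarray:
        """Flatten to an (n_cells, n_drivers) design matrix."""
        return self.data.reshape(self.data.shape[0], -1).T


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def write_ascii_grid(
    path: str | Path,
    array: np.ndarray,
    cell_size: float = 100.0,
    nodata: float = NODATA,
    fmt: str = "%d",
) -> None:
    path = Path(path)
    rows, cols = array.shape
    header = (
        f"ncols {cols}\n"
        f"nrows {rows}\n"
        "xllcorner 0.0\n"
        "yllcorner 0.0\n"
        f"cellsize {cell_size}\n"
        f"NODATA_value {nodata}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, array, fmt=fmt)


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float, float]:
    """Read an ESRI ASCII grid; returns (array, cellsize, nodata)."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, value = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"}:
                header[key] = float(value)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        body = np.loadtxt(fh)
    body = np.atleast_2d(body)
    return body, header.get("cellsize", 100.0), header.get("nodata_value", NODATA)


def save_landuse(path: str | Path, grid: LandUseGrid) -> None:
    write_ascii_grid(path, grid.data, cell_size=grid.cell_size)


def load_landuse(path: str | Path, cell_area: float | None = None) -> LandUseGrid:
    arr, cellsize, _ = read_ascii_grid(path)
    if cell_area is None:
        cell_area = cellsize**2 / 1e4  # m^2 -> ha
    return LandUseGrid(arr.astype(np.int64), cell_area=cell_area, cell_size=cellsize)


def save_drivers(directory: str | Path, stem: str, stack: DriverStack,
                 cell_size: float = 100.0) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, band in zip(stack.names, stack.data):
        write_ascii_grid(directory / f"{stem}.{name}.asc", band,
                         cell_size=cell_size, nodata=-9999, fmt="%.6f")
    (directory / f"{stem}.bands.txt").write_text("\n".join(stack.names) + "\n")


def load_drivers(directory: str | Path, stem: str) -> DriverStack:
    directory = Path(directory)
    names = (directory / f"{stem}.bands.txt").read_text().split()
    bands = [read_ascii_grid(directory / f"{stem}.{n}.asc")[0] for n in names]
    return DriverStack(tuple(names), np.stack(bands))
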