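"""Georeferenced grid rasters and ESRI ASCII grid serialization.

A :class:`GridRaster` holds a rectangular cell matrix in a projected CRS
(coordinates in meters).  Row 0 is the *northernmost* row, matching the
ESRI ASCII grid convention; ``origin`` is the (x, y) of the lower-left
corner of the grid.  Nodata cells are represented as ``NaN`` in a float
array regardless of the nodata sentinel used on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["GridRaster", "read_ascii_grid", "write_ascii_grid"]

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


@dataclass
class GridRaster:
    """A rectangular raster of cells with a fixed cell size.

    Parameters
    ----------
    values
        2-D float array; ``values[0, :]`` is the northernmost row.
        ``NaN`` marks nodata.
    cell_size
        Edge length of one (square) cell, in meters.  Must be positive.
    origin
        ``(x, y)`` of the lower-left corner of the lower-left cell.
    role
        Free-form tag describing what the raster encodes:
        ``"habitat"`` (binary 0/1), ``"dem"`` (elevation m),
        ``"resistance"`` (cost per meter, > 0) or ``"slope"`` (rise/run).
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    role: str = field(default="generic")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    # -- geometry ---------------------------------------------------------
    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster footprint."""
        x0, y0 = self.origin
        return (x0, y0,
                x0 + self.ncols * self.cell_size,
                y0 + self.nrows * self.cell_size)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        x = x0 + (col + 0.5) * self.cell_size
        y = y0 + (self.nrows - 1 - row + 0.5) * self.cell_size
        return (x, y)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (xs, ys) of cell-center coordinates, shaped like values."""
        x0, y0 = self.origin
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        xs = x0 + (cols + 0.5) * self.cell_size
        ys = y0 + (self.nrows - 1 - rows + 0.5) * self.cell_size
        return np.broadcast_to(xs, self.values.shape).copy(), \
            np.broadcast_to(ys[:, None], self.values.shape).copy()

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing point (x, y)."""
        xmin, ymin, xmax, ymax = self.extent
        if not (xmin <= x <= xmax and ymin <= y <= ymax):
            raise ValueError(f"point ({x}, {y}) outside raster extent {self.extent}")
        col = min(int((x - xmin) / self.cell_size), self.ncols - 1)
        row = min(int((ymax - y) / self.cell_size), self.nrows - 1)
        return (row, col)

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.extent
        return xmin <= x <= xmax and ymin <= y <= ymax

    def aligned_with(self, other: "GridRaster") -> bool:
        return (self.values.shape == other.values.shape
                and np.isclose(self.cell_size, other.cell_size)
                and np.allclose(self.origin, other.origin))

    def copy(self, values: np.ndarray | None = None,
             role: str | None = None) -> "GridRaster":
        return GridRaster(
            values=self.values.copy() if values is None else np.asarray(values, float),
            cell_size=self.cell_size,
            origin=self.origin,
            role=self.role if role is None else role,
        )


def read_ascii_grid(path: str | Path, role: str = "generic") -> GridRaster:
    """Read an ESRI ASCII grid (six-line header + row-major values).

    The header must provide ncols, nrows, xllcorner, yllcorner and cellsize;
    NODATA_value is optional (defaults to -9999).  Nodata cells become NaN.
    """
    path = Path(path)
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with path.open() as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not data_lines and key in _HEADER_KEYS + ("nodata_value",):
                if len(parts) != 2:
                    raise ValueError(f"{path}: malformed header line {line!r}")
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise ValueError(f"{path}: ASCII grid header missing {missing}")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    nodata = header.get("nodata_value", -9999.0)
    try:
        flat = np.array(" ".join(data_lines).split(), dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: could not parse grid values") from exc
    if flat.size != nrows * ncols:
        raise ValueError(
            f"{path}: expected {nrows * ncols} values, found {flat.size}")
    values = flat.reshape(nrows, ncols)
    values[values == nodata] = np.nan
    return GridRaster(values=values, cell_size=header["cellsize"],
                      origin=(header["xllcorner"], header["yllcorner"]),
                      role=role)


def write_ascii_grid(raster: GridRaster, path: str | Path,
                     nodata: float = -9999.0) -> None:
    """Write a GridRaster as an ESRI ASCII grid (NaN -> nodata sentinel)."""
    path = Path(path)
    vals = raster.values.copy()
    vals[np.isnan(vals)] = nodata
    with path.open("w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.origin[0]:.6f}\n")
        fh.write(f"yllcorner {raster.origin[1]:.6f}\n")
        fh.write(f"cellsize {raster.cell_size:.6f}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.10g}" for v in row))
            fh.write("\n")
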