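"""Categorical raster container and plain-text (ESRI ASCII grid) I/O.

All geospatial work here happens on planar, meter-based grids — the study
landscapes are 30 m land-cover grids in a local projected CRS — so the
container is deliberately minimal: an integer class grid, a cell size, and
the lower-left corner. No CRS handling or reprojection is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA_DEFAULT = -9999


@dataclass
class CategoricalRaster:
    """Class-coded grid. Row 0 is the northernmost row (raster convention)."""

    data: np.ndarray  # 2-D integer array
    cell_size: float  # meters
    xll: float = 0.0  # x of lower-left corner
    yll: float = 0.0  # y of lower-left corner
    nodata: int = NODATA_DEFAULT
    legend: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the outer cell edges."""
        nr, nc = self.data.shape
        return (self.xll, self.xll + nc * self.cell_size,
                self.yll, self.yll + nr * self.cell_size)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (X, Y) of cell-center coordinates, shaped like ``data``."""
        nr, nc = self.data.shape
        xs = self.xll + (np.arange(nc) + 0.5) * self.cell_size
        ys = self.yll + (nr - np.arange(nr) - 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def cell_at(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing planar point (x, y)."""
        nr, nc = self.data.shape
        col = int(np.floor((x - self.xll) / self.cell_size))
        row = int(nr - 1 - np.floor((y - self.yll) / self.cell_size))
        if not (0 <= row < nr and 0 <= col < nc):
            raise ValueError(f"point ({x}, {y}) outside raster extent")
        return row, col

    def valid_mask(self) -> np.ndarray:
        return self.data != self.nodata

    def code_of(self, cls: int | str) -> int:
        if isinstance(cls, str):
            try:
                return self.legend[cls]
            except KeyError:
                raise KeyError(f"class {cls!r} not in raster legend") from None
        return int(cls)


def write_ascii_grid(raster: CategoricalRaster, path: str | Path) -> None:
    """Write an ESRI ASCII grid (.asc)."""
    nr, nc = raster.data.shape
    header = (
        f"ncols {nc}\n"
        f"nrows {nr}\n"
        f"xllcorner {raster.xll}\n"
        f"yllcorner {raster.yll}\n"
        f"cellsize {raster.cell_size}\n"
        f"NODATA_value {raster.nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.data, fmt="%d")


def read_ascii_grid(path: str | Path) -> CategoricalRaster:
    """Read an ESRI ASCII grid (.asc)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"}:
                header[key] = float(val)
                pos = fh.tell()
            else:  # optional NODATA line absent
                break
        fh.seek(pos)
        data = np.loadtxt(fh, dtype=int)
    data = np.atleast_2d(data)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"grid shape {data.shape} does not match header")
    return CategoricalRaster(
        data=data,
        cell_size=header["cellsize"],
        xll=header.get("xllcorner", 0.0),
        yll=header.get("yllcorner", 0.0),
        nodata=int(header.get("nodata_value", NODATA_DEFAULT)),
    )
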