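"""Categorical landcover raster with ESRI ASCII grid I/O.

The analysis uses an NLCD-like grid (30 m cells) condensed to three
coarse habitat classes — bottomland, upland pine, shrub/grassland —
plus an ``excluded`` code covering developed, cultivated, open-water
and barren cells, which are dropped from selection analyses.

Cells use a half-open convention: a point on the shared edge of two
cells belongs to the cell on the right/above in grid coordinates,
i.e. ``col = floor((x - x0) / cell)``. Row 0 is the northernmost row,
as in the ESRI ASCII format.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BOTTOMLAND = "bottomland"
UPLAND_PINE = "upland_pine"
GRASSLAND = "grassland"
EXCLUDED = "excluded"

#: Integer codes used on disk and in the grid array.
CLASS_CODES = {BOTTOMLAND: 1, UPLAND_PINE: 2, GRASSLAND: 3, EXCLUDED: 9}
CODE_CLASSES = {v: k for k, v in CLASS_CODES.items()}
NODATA = -9999


@dataclass
class LandscapeRaster:
    """3-class habitat grid in a projected metric CRS.

    ``origin`` is the (x, y) of the lower-left corner of the lower-left
    cell; ``grid`` holds integer class codes with row 0 at the top
    (north), matching ESRI ASCII row order.
    """

    origin: tuple[float, float]
    cell_size: float
    grid: np.ndarray  # (nrows, ncols) int codes

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int16)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full grid."""
        nr, nc = self.grid.shape
        x0, y0 = self.origin
        return (x0, y0, x0 + nc * self.cell_size, y0 + nr * self.cell_size)

    def rowcol(self, x, y):
        """Grid indices of point(s); half-open cells, row 0 at top."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        nr, nc = self.grid.shape
        col = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        row = (nr - 1) - np.floor((y - self.origin[1]) / self.cell_size).astype(int)
        return row, col

    def contains(self, x, y):
        row, col = self.rowcol(x, y)
        nr, nc = self.grid.shape
        return (row >= 0) & (row < nr) & (col >= 0) & (col < nc)

    def code_at(self, x, y):
        """Class code at point(s); NODATA for points off the raster."""
        row, col = self.rowcol(x, y)
        nr, nc = self.grid.shape
        inside = (row >= 0) & (row < nr) & (col >= 0) & (col < nc)
        out = np.full(np.shape(inside), NODATA, dtype=int)
        out[inside] = self.grid[row[inside], col[inside]]
        if np.isscalar(x) or np.ndim(x) == 0:
            return int(out.reshape(-1)[0])
        return out

    def class_at(self, x: float, y: float) -> str | None:
        """Habitat class name at a single point, None if off-raster."""
        code = self.code_at(x, y)
        return CODE_CLASSES.get(code)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates (xs, ys) aligned with grid rows/cols."""
        nr, nc = self.grid.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(nc) + 0.5) * self.cell_size
        ys = y0 + ((nr - 1 - np.arange(nr)) + 0.5) * self.cell_size
        return xs, ys

    def class_fractions(self) -> dict[str, float]:
        """Fraction of cells per class over the whole grid."""
        total = self.grid.size
        return {
            name: float((self.grid == code).sum()) / total
            for name, code in CLASS_CODES.items()
        }

    def write_ascii(self, path) -> None:
        """Write the grid as an ESRI ASCII (.asc) file."""
        nr, nc = self.grid.shape
        header = (
            f"ncols {nc}\n"
            f"nrows {nr}\n"
            f"xllcorner {self.origin[0]:.6f}\n"
            f"yllcorner {self.origin[1]:.6f}\n"
            f"cellsize {self.cell_size:.6f}\n"
            f"NODATA_value {NODATA}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.grid, fmt="%d")

    @classmethod
    def read_ascii(cls, path) -> "LandscapeRaster":
        """Read an ESRI ASCII grid (integer class codes)."""
        header: dict[str, float] = {}
        with open(path) as fh:
            pos = fh.tell()
            for _ in range(6):
                line = fh.readline()
                key, val = line.split()
                key = key.lower()
                if key in ("ncols", "nrows", "xllcorner", "yllcorner",
                           "cellsize", "nodata_value"):
                    header[key] = float(val)
                    pos = fh.tell()
                else:
                    break
            fh.seek(pos)
            grid = np.loadtxt(fh, dtype=np.int16)
        grid = np.atleast_2d(grid)
        if "xllcenter" in header:  # rare variant
            header["xllcorner"] = header["xllcenter"] - header["cellsize"] / 2
        nr, nc = int(header["nrows"]), int(header["ncols"])
        if grid.shape != (nr, nc):
            raise ValueError(f"grid shape {grid.shape} != header ({nr}, {nc})")
        return cls(
            origin=(header["xllcorner"], header["yllcorner"]),
            cell_size=header["cellsize"],
            grid=grid,
        )
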