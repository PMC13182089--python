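"""Lightweight categorical raster on a regular metric grid.

The habitat map is a single-band integer raster in a projected CRS
(metres).  Values are habitat class codes; the generator uses
1=grassland, 2=floodplain, 3=mixed woodland, 4=mopane.  I/O is the
ESRI ASCII grid format, which keeps fixtures plain text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

HABITAT_LEGEND = {1: "grassland", 2: "floodplain", 3: "mixed_woodland", 4: "mopane"}


@dataclass
class Raster:
    """Regular grid with lower-left corner ``(xll, yll)`` and square cells.

    ``data`` is stored row 0 = northernmost row (the ASCII-grid layout).
    """

    data: np.ndarray
    xll: float
    yll: float
    cellsize: float
    nodata: int = -9999

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        return (
            self.xll,
            self.yll,
            self.xll + self.ncols * self.cellsize,
            self.yll + self.nrows * self.cellsize,
        )

    def contains(self, x, y) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.bounds
        return (np.asarray(x) >= xmin) & (np.asarray(x) < xmax) & (
            np.asarray(y) >= ymin
        ) & (np.asarray(y) < ymax)

    def sample(self, x, y):
        """Class code at point(s); raises if any point is outside the grid."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if not np.all(self.contains(x, y)):
            raise ValueError("point outside raster extent")
        col = np.floor((x - self.xll) / self.cellsize).astype(int)
        row = self.nrows - 1 - np.floor((y - self.yll) / self.cellsize).astype(int)
        return self.data[row, col]

    def write_ascii(self, path: str | Path) -> None:
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {self.xll}\n"
            f"yllcorner {self.yll}\n"
            f"cellsize {self.cellsize}\n"
            f"NODATA_value {self.nodata}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.data, fmt="%d")

    @classmethod
    def read_ascii(cls, path: str | Path) -> "Raster":
        meta: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            data = np.loadtxt(fh)
        data = np.atleast_2d(data).astype(int)
        return cls(
            data=data,
            xll=meta["xllcorner"],
            yll=meta["yllcorner"],
            cellsize=meta["cellsize"],
            nodata=int(meta.get("nodata_value", -9999)),
        )
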