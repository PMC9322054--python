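"""Green-space density from a categorical land-use grid.

Green space is defined as woodland, shrubland, grassland or wetland; the
density of an area is the fraction of its (non-no-data) land-use cells whose
class is green. Cell membership is decided by the cell centre falling inside
the area polygon; at 10 m resolution the difference from area-weighted
partial cells is negligible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

__all__ = [
    "LandUseGrid",
    "NoOverlapError",
    "GREEN_CLASSES",
    "green_space_density",
    "read_ascii_grid",
    "write_ascii_grid",
]

GREEN_CLASSES = frozenset({"woodland", "shrubland", "grassland", "wetland"})


class NoOverlapError(ValueError):
    """The area overlaps no non-no-data grid cell."""


@dataclass
class LandUseGrid:
    """Categorical land-use raster on a regular north-up grid.

    ``codes`` is (nrows, ncols) with row 0 the northernmost row (ESRI ASCII
    convention). ``legend`` maps integer codes to class names; classes whose
    name is in ``green_classes`` count as green space.
    """

    codes: np.ndarray
    cellsize: float
    xllcorner: float
    yllcorner: float
    nodata: int
    legend: Mapping[int, str]
    green_classes: frozenset[str] = GREEN_CLASSES

    def __post_init__(self):
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D array")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")
        known = set(self.legend) | {self.nodata}
        present = set(np.unique(self.codes).tolist())
        if not present <= known:
            raise ValueError(f"codes without legend entry: {sorted(present - known)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) centre coordinates, same shape as ``codes``."""
        nrows, ncols = self.codes.shape
        x = self.xllcorner + (np.arange(ncols) + 0.5) * self.cellsize
        y = self.yllcorner + (nrows - np.arange(nrows) - 0.5) * self.cellsize
        return np.meshgrid(x, y)

    def green_codes(self) -> np.ndarray:
        return np.array([c for c, name in self.legend.items()
                         if name in self.green_classes], dtype=self.codes.dtype)


def green_space_density(grid: LandUseGrid, area) -> float:
    """Fraction of green cells among an area's non-no-data cells.

    ``area`` is a shapely polygon (cell-centre-in-polygon membership) or a
    boolean cell mask of the grid's shape. No-data cells are excluded from
    numerator and denominator alike.
    """
    if isinstance(area, BaseGeometry):
        X, Y = grid.cell_centers()
        inside = shapely.contains_xy(area, X.ravel(), Y.ravel()).reshape(grid.shape)
    else:
        inside = np.asarray(area, dtype=bool)
        if inside.shape != grid.shape:
            raise ValueError("mask shape does not match grid")
    valid = inside & (grid.codes != grid.nodata)
    total = int(valid.sum())
    if total == 0:
        raise NoOverlapError("area overlaps no non-no-data cell")
    green = int((valid & np.isin(grid.codes, grid.green_codes())).sum())
    return green / total


def read_ascii_grid(path, legend: Mapping[int, str] | str | Path,
                    green_classes: frozenset[str] = GREEN_CLASSES) -> LandUseGrid:
    """Read an ESRI ASCII grid plus a JSON legend (code -> class name)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        codes = np.loadtxt(fh, dtype=int)
    codes = np.atleast_2d(codes)
    if codes.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("grid body does not match declared nrows/ncols")
    if not isinstance(legend, Mapping):
        with open(legend) as fh:
            legend = {int(k): v for k, v in json.load(fh).items()}
    return LandUseGrid(
        codes=codes,
        cellsize=header["cellsize"],
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        nodata=int(header["nodata_value"]),
        legend=dict(legend),
        green_classes=green_classes,
    )


def write_ascii_grid(grid: LandUseGrid, path, legend_path=None) -> None:
    nrows, ncols = grid.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\nnrows {nrows}\n")
        fh.write(f"xllcorner {grid.xllcorner!r}\nyllcorner {grid.yllcorner!r}\n")
        fh.write(f"cellsize {grid.cellsize!r}\nNODATA_value {grid.nodata}\n")
        np.savetxt(fh, grid.codes, fmt="%d")
    if legend_path is not None:
        with open(legend_path, "w") as fh:
            json.dump({str(k): v for k, v in grid.legend.items()}, fh, indent=1)
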