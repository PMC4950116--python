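"""Plate-carrée grid geometry and plain-text raster I/O.

Grids are plain 2-D numpy arrays (row 0 = southernmost row) with a small
:class:`GridGeometry` describing cell size and origin in decimal degrees.
Rasters are written as whitespace-separated text matrices with a JSON
sidecar (``<name>.json``) holding the geometry, so every artefact stays
human-readable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

__all__ = ["GridGeometry", "read_grid", "write_grid", "aggregate_to_coarse"]


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of a regular lon/lat grid (plate carrée cell arithmetic).

    Parameters
    ----------
    origin_x, origin_y:
        West and south edges of the grid, decimal degrees.
    cell_size:
        Edge length of a (square) cell in degrees.
    nrows, ncols:
        Grid dimensions; row index increases northward.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    nrows: int
    ncols: int

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.ncols) + 0.5) * self.cell_size

    @property
    def y_centers(self) -> np.ndarray:
        return self.origin_y + (np.arange(self.nrows) + 0.5) * self.cell_size

    def cell_of(self, lon, lat):
        """Map coordinates to (row, col); returns -1 for out-of-extent points."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((lat - self.origin_y) / self.cell_size).astype(int)
        bad = (col < 0) | (col >= self.ncols) | (row < 0) | (row >= self.nrows)
        row = np.where(bad, -1, row)
        col = np.where(bad, -1, col)
        return row, col

    def coarsen(self, factor: int) -> "GridGeometry":
        if self.nrows % factor or self.ncols % factor:
            raise ValueError(
                f"aggregation factor {factor} does not divide grid shape {self.shape}"
            )
        return GridGeometry(
            origin_x=self.origin_x,
            origin_y=self.origin_y,
            cell_size=self.cell_size * factor,
            nrows=self.nrows // factor,
            ncols=self.ncols // factor,
        )


def aggregate_to_coarse(grid: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean aggregation of a fine grid to a coarser resolution.

    Each coarse cell is the arithmetic mean of its ``factor x factor``
    fine cells; the factor must divide both grid dimensions exactly.
    """
    grid = np.asarray(grid, dtype=float)
    if factor < 1:
        raise ValueError("factor must be a positive integer")
    nr, nc = grid.shape
    if nr % factor or nc % factor:
        raise ValueError(
            f"aggregation factor {factor} does not divide grid shape {grid.shape}"
        )
    return grid.reshape(nr // factor, factor, nc // factor, factor).mean(axis=(1, 3))


def write_grid(path: str | Path, grid: np.ndarray, geometry: GridGeometry) -> None:
    path = Path(path)
    np.savetxt(path, np.asarray(grid, dtype=float), fmt="%.10g")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(asdict(geometry), indent=1))


def read_grid(path: str | Path) -> tuple[np.ndarray, GridGeometry]:
    path = Path(path)
    grid = np.atleast_2d(np.loadtxt(path))
    sidecar = path.with_suffix(path.suffix + ".json")
    geometry = GridGeometry(**json.loads(sidecar.read_text()))
    if grid.shape != geometry.shape:
        raise ValueError(
            f"grid file {path} has shape {grid.shape} but sidecar declares {geometry.shape}"
        )
    return grid, geometry
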