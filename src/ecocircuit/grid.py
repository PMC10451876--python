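"""Raster grid primitives and plain-text I/O.

All rasters in one analysis live on a single :class:`GridSpec` — a regular
planar grid with square cells, addressed (row, col) from the top-left corner.
Rasters are stored as 2-D numpy arrays with an explicit boolean validity
mask. On disk, rasters use the ESRI ASCII grid format (``.asc``) and vector
data uses GeoJSON, so every artifact is a text file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np


class GridSpecError(ValueError):
    """Invalid grid specification (non-positive dimensions or cell size)."""


class GridAlignmentError(ValueError):
    """Rasters that must share a GridSpec do not."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the analysis grid.

    Parameters
    ----------
    nrows, ncols:
        Grid dimensions; at least 2 each.
    cell_size:
        Cell edge length in metres.
    origin:
        ``(x, y)`` planar coordinates of the *top-left corner* of the grid.
    nodata_value:
        Sentinel written to ``.asc`` files for masked cells.
    """

    nrows: int
    ncols: int
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        if self.nrows < 2 or self.ncols < 2:
            raise GridSpecError(
                f"grid must be at least 2x2, got {self.nrows}x{self.ncols}"
            )
        if self.cell_size <= 0:
            raise GridSpecError(f"cell_size must be positive, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    def cell_area_km2(self) -> float:
        return self.cell_size**2 / 1e6

    def cell_center(self, row, col):
        """Planar (x, y) of cell centers; accepts scalars or arrays."""
        x0, y0 = self.origin
        x = x0 + (np.asarray(col) + 0.5) * self.cell_size
        y = y0 - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrids (X, Y) of all cell-center coordinates, shape (nrows, ncols)."""
        rows, cols = np.mgrid[0 : self.nrows, 0 : self.ncols]
        return self.cell_center(rows, cols)

    def cell_of_point(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing a planar point."""
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row = int(np.floor((y0 - y) / self.cell_size))
        return row, col

    def contains_point(self, x: float, y: float) -> bool:
        row, col = self.cell_of_point(x, y)
        return 0 <= row < self.nrows and 0 <= col < self.ncols


@dataclass
class Raster:
    """A 2-D array bound to a :class:`GridSpec` with a validity mask."""

    values: np.ndarray
    spec: GridSpec
    mask: np.ndarray = field(default=None)  # True = valid cell

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.spec.shape:
            raise GridAlignmentError(
                f"values shape {self.values.shape} != grid {self.spec.shape}"
            )
        if self.mask is None:
            self.mask = np.ones(self.spec.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.spec.shape:
                raise GridAlignmentError("mask shape does not match grid")

    def same_grid(self, *others: "Raster") -> None:
        for other in others:
            if other.spec != self.spec:
                raise GridAlignmentError(
                    f"rasters on different grids: {self.spec} vs {other.spec}"
                )

    def copy_with(self, values: np.ndarray, mask: np.ndarray | None = None) -> "Raster":
        return Raster(values=np.array(values), spec=self.spec,
                      mask=self.mask.copy() if mask is None else mask)

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]


def write_asc(raster: Raster, path: str | Path) -> None:
    """Write a raster as an ESRI ASCII grid (plain text)."""
    spec = raster.spec
    x0, y0 = spec.origin
    vals = np.where(raster.mask, raster.values, spec.nodata_value)
    header = (
        f"ncols {spec.ncols}\n"
        f"nrows {spec.nrows}\n"
        f"xllcorner {x0}\n"
        f"yllcorner {y0 - spec.nrows * spec.cell_size}\n"
        f"cellsize {spec.cell_size}\n"
        f"NODATA_value {spec.nodata_value}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_asc(path: str | Path, dtype=float) -> Raster:
    """Read an ESRI ASCII grid into a :class:`Raster`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    cell = header["cellsize"]
    nodata = header.get("nodata_value", -9999.0)
    spec = GridSpec(
        nrows=nrows,
        ncols=ncols,
        cell_size=cell,
        origin=(header["xllcorner"], header["yllcorner"] + nrows * cell),
        nodata_value=nodata,
    )
    data = data.reshape(nrows, ncols)
    mask = data != nodata
    return Raster(values=data.astype(dtype), spec=spec, mask=mask)


def points_to_geojson(points: np.ndarray, path: str | Path | None = None) -> dict:
    """Serialize an (n, 2) array of planar (x, y) points as GeoJSON."""
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
            "properties": {"id": i},
        }
        for i, (x, y) in enumerate(np.atleast_2d(points))
    ]
    obj = {"type": "FeatureCollection", "features": features}
    if path is not None:
        Path(path).write_text(json.dumps(obj))
    return obj


def points_from_geojson(source: str | Path | dict) -> np.ndarray:
    """Load Point features from GeoJSON into an (n, 2) array."""
    if not isinstance(source, dict):
        source = json.loads(Path(source).read_text())
    coords = [
        f["geometry"]["coordinates"]
        for f in source["features"]
        if f["geometry"]["type"] == "Point"
    ]
    return np.asarray(coords, dtype=float).reshape(-1, 2)
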