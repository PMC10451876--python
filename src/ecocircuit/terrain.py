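"""Terrain factor rasters derived from the DEM: slope and roughness.

Slope uses Horn's 3x3 finite-difference operator (the common GIS default),
reported in degrees. Terrain roughness is the surface-to-planar area ratio
1 / cos(slope), a dimensionless value >= 1 that equals 1 on flat ground.
Border cells are handled by edge replication so the output grid does not
shrink.
"""

from __future__ import annotations

import numpy as np

from .grid import GridSpecError, Raster


class TerrainDomainError(ValueError):
    """Slope outside [0, 90) where roughness is undefined."""


def compute_slope(dem: Raster, cell_size: float | None = None) -> Raster:
    """Slope in degrees from a DEM via Horn's 3x3 method.

    Parameters
    ----------
    dem:
        Elevation raster in metres.
    cell_size:
        Cell edge in metres; defaults to the DEM's grid cell size.
    """
    if cell_size is None:
        cell_size = dem.spec.cell_size
    if cell_size <= 0:
        raise GridSpecError(f"cell_size must be positive, got {cell_size}")

    z = np.pad(dem.values.astype(float), 1, mode="edge")
    # 3x3 neighbours: a b c / d e f / g h i
    a = z[:-2, :-2]; b = z[:-2, 1:-1]; c = z[:-2, 2:]
    d = z[1:-1, :-2];                  f = z[1:-1, 2:]
    g = z[2:, :-2];  h = z[2:, 1:-1];  i = z[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cell_size)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8 * cell_size)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    return dem.copy_with(slope)


def compute_roughness(slope: Raster) -> Raster:
    """Terrain roughness = 1 / cos(slope), per cell.

    Strictly increasing in slope; 1.0 on flat terrain. Slopes at or above
    90 degrees are rejected (the ratio diverges).
    """
    s = slope.values[slope.mask]
    if s.size and (s.min() < 0 or s.max() >= 90):
        raise TerrainDomainError(
            f"slope must lie in [0, 90) degrees, got range "
            f"[{s.min():.3g}, {s.max():.3g}]"
        )
    rough = np.ones_like(slope.values, dtype=float)
    rough[slope.mask] = 1.0 / np.cos(np.radians(s))
    return slope.copy_with(rough)
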