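"""Ecological resistance surface: factor classification and superposition.

Four factors hinder large-herbivore dispersal: elevation, slope, terrain
roughness and land-use type. Each factor raster is classified into discrete
resistance values (10 … 10,000), and the combined resistance surface is the
equal-weight superposition — the arithmetic mean — of the four factor-value
rasters. The default classification ships as a YAML file
(``ecocircuit/data/table1.yaml``) and can be overridden.

Continuous class intervals are lower-closed, upper-open: a slope of exactly
15 degrees falls in the 15–30 class.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .grid import Raster

#: CNLUCC-style woodland + grassland codes, used for the forest+grassland
#: aggregate row of zonal composition tables.
FOREST_GRASS_CODES = frozenset({21, 22, 23, 24, 31, 32, 33})


class ClassificationError(ValueError):
    """A raster value has no matching class / code mapping."""


@dataclass(frozen=True)
class FactorClassification:
    """Classification rules for one resistance factor.

    Either continuous (``breaks`` + ``values``, intervals lower-closed) or
    categorical (``code_values``: land-use code -> resistance value).
    """

    factor_name: str
    breaks: tuple[float, ...] | None = None
    values: tuple[float, ...] | None = None
    code_values: dict[int, float] | None = None

    def __post_init__(self) -> None:
        if self.code_values is None:
            if self.breaks is None or self.values is None:
                raise ClassificationError(
                    f"{self.factor_name}: need breaks+values or code_values"
                )
            if len(self.values) != len(self.breaks) + 1:
                raise ClassificationError(
                    f"{self.factor_name}: {len(self.breaks)} breaks require "
                    f"{len(self.breaks) + 1} values, got {len(self.values)}"
                )
            if list(self.breaks) != sorted(self.breaks):
                raise ClassificationError(f"{self.factor_name}: breaks not ascending")

    @property
    def is_categorical(self) -> bool:
        return self.code_values is not None

    def lookup(self, values: np.ndarray) -> np.ndarray:
        """Resistance value per element; raises on unmapped categorical codes."""
        values = np.asarray(values)
        if self.is_categorical:
            codes = np.unique(values)
            unknown = sorted(int(c) for c in codes if int(c) not in self.code_values)
            if unknown:
                raise ClassificationError(
                    f"{self.factor_name}: codes with no resistance mapping: {unknown}"
                )
            lut_codes = np.array(sorted(self.code_values))
            lut_vals = np.array([self.code_values[c] for c in sorted(self.code_values)],
                                dtype=float)
            return lut_vals[np.searchsorted(lut_codes, values.astype(int))]
        # lower-closed intervals: count of breaks <= x selects the class
        idx = np.searchsorted(np.asarray(self.breaks), values, side="right")
        return np.asarray(self.values, dtype=float)[idx]


@dataclass
class ResistanceConfig:
    """The full four-factor classification table."""

    elevation: FactorClassification
    slope: FactorClassification
    roughness: FactorClassification
    landuse: FactorClassification

    @property
    def landuse_groups(self) -> dict[str, dict]:
        return dict(self._groups)

    def group_of_code(self, code: int) -> str | None:
        for name, g in self._groups.items():
            if code in g["codes"]:
                return name
        return None


def _factor_from_dict(name: str, d: dict) -> FactorClassification:
    if d.get("kind", "continuous") == "categorical":
        code_values: dict[int, float] = {}
        for g in d["groups"].values():
            for code in g["codes"]:
                code_values[int(code)] = float(g["value"])
        return FactorClassification(factor_name=name, code_values=code_values)
    return FactorClassification(
        factor_name=name, breaks=tuple(d["breaks"]), values=tuple(d["values"])
    )


def load_classification(path: str | Path | None = None) -> ResistanceConfig:
    """Load the factor classification table (default: the packaged YAML)."""
    if path is None:
        text = resources.files("ecocircuit").joinpath("data/table1.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    cfg = ResistanceConfig(
        elevation=_factor_from_dict("elevation", raw["elevation"]),
        slope=_factor_from_dict("slope", raw["slope"]),
        roughness=_factor_from_dict("roughness", raw["roughness"]),
        landuse=_factor_from_dict("landuse", raw["landuse"]),
    )
    cfg._groups = {k: dict(v) for k, v in raw["landuse"]["groups"].items()}
    return cfg


def classify_factor(raster: Raster, classification: FactorClassification) -> Raster:
    """Map a factor raster to its per-cell resistance values.

    Invalid (masked) cells are passed through as masked; categorical codes
    outside the mapping raise :class:`ClassificationError` naming the codes.
    """
    out = np.zeros(raster.spec.shape, dtype=float)
    if raster.mask.any():
        out[raster.mask] = classification.lookup(raster.values[raster.mask])
    return raster.copy_with(out)


def superpose(
    elev_r: Raster,
    slope_r: Raster,
    rough_r: Raster,
    landuse_r: Raster,
    cap: float | None = None,
) -> Raster:
    """Equal-weight superposition of the four classified factor rasters.

    The combined resistance of a cell is the arithmetic mean of its four
    factor values; a cell masked in any factor is masked in the output.
    ``cap`` optionally clips each factor value before averaging (sensitivity
    analysis for workflows that bound the extreme class).
    """
    elev_r.same_grid(slope_r, rough_r, landuse_r)
    stack = np.stack([r.values.astype(float) for r in (elev_r, slope_r, rough_r, landuse_r)])
    if cap is not None:
        stack = np.minimum(stack, cap)
    mask = elev_r.mask & slope_r.mask & rough_r.mask & landuse_r.mask
    combined = stack.mean(axis=0)
    combined[~mask] = 0.0
    return Raster(values=combined, spec=elev_r.spec, mask=mask)


def build_resistance_surface(
    dem: Raster,
    landuse: Raster,
    config: ResistanceConfig | None = None,
    cap: float | None = None,
) -> tuple[Raster, dict[str, Raster]]:
    """DEM + land use -> combined resistance surface.

    Derives slope and roughness from the DEM, classifies all four factors,
    and superposes them. Returns ``(combined, factor_rasters)`` where the
    dict holds the four per-factor resistance-value rasters (provenance).
    """
    from .terrain import compute_roughness, compute_slope

    if config is None:
        config = load_classification()
    slope = compute_slope(dem, dem.spec.cell_size)
    rough = compute_roughness(slope)
    factors = {
        "elevation": classify_factor(dem, config.elevation),
        "slope": classify_factor(slope, config.slope),
        "roughness": classify_factor(rough, config.roughness),
        "landuse": classify_factor(landuse, config.landuse),
    }
    combined = superpose(
        factors["elevation"], factors["slope"], factors["roughness"],
        factors["landuse"], cap=cap,
    )
    return combined, factors
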