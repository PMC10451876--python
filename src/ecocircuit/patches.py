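"""Ecological patches: the habitat regions acting as network terminals.

Type I patches hold the focal species (reserves with resident elephants);
type II patches are suitable alternative habitat. Both enter the circuit
solver as terminals with equal standing; type I additionally seeds the
pinch-point buffer. Patches are polygons rasterized by the cell-center rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .grid import GridSpec, Raster

PATCH_TYPES = ("I", "II")


class PatchError(ValueError):
    pass


class DegeneratePatchError(PatchError):
    """A patch covers no cell center on the analysis grid."""


class PatchOverlapError(PatchError):
    """Two patches claim the same grid cell."""


@dataclass(frozen=True)
class Patch:
    id: int
    type: str  # "I" or "II"
    geometry: BaseGeometry

    def __post_init__(self) -> None:
        if self.type not in PATCH_TYPES:
            raise PatchError(f"patch {self.id}: type must be I or II, got {self.type!r}")
        if self.id <= 0:
            raise PatchError(f"patch ids must be positive integers, got {self.id}")


@dataclass
class PatchSet:
    patches: list[Patch] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.patches]
        if len(set(ids)) != len(ids):
            raise PatchError(f"duplicate patch ids: {sorted(ids)}")

    def __len__(self) -> int:
        return len(self.patches)

    def __iter__(self):
        return iter(self.patches)

    def by_type(self, ptype: str) -> list[Patch]:
        return [p for p in self.patches if p.type == ptype]

    @property
    def ids(self) -> list[int]:
        return [p.id for p in self.patches]

    def types_by_id(self) -> dict[int, str]:
        return {p.id: p.type for p in self.patches}


def rasterize_patches(patches: PatchSet, spec: GridSpec) -> Raster:
    """Label raster: cell = patch id where the cell center falls inside the
    patch polygon, 0 elsewhere.

    A patch covering no cell center raises :class:`DegeneratePatchError`;
    two patches covering one cell raise :class:`PatchOverlapError`.
    """
    labels = np.zeros(spec.shape, dtype=int)
    X, Y = spec.cell_centers()
    for patch in patches:
        inside = shapely.contains_xy(patch.geometry, X.ravel(), Y.ravel()).reshape(
            spec.shape
        )
        if not inside.any():
            raise DegeneratePatchError(
                f"patch {patch.id} covers no cell center at cell size "
                f"{spec.cell_size}"
            )
        clash = inside & (labels != 0)
        if clash.any():
            other = int(labels[clash][0])
            raise PatchOverlapError(
                f"patches {other} and {patch.id} overlap on the grid"
            )
        labels[inside] = patch.id
    return Raster(values=labels, spec=spec)


def patch_areas(labeled: Raster, patches: PatchSet | None = None) -> pd.DataFrame:
    """Per-patch cell counts and areas (km^2) from a label raster."""
    spec = labeled.spec
    ids, counts = np.unique(labeled.values[labeled.values > 0], return_counts=True)
    types = patches.types_by_id() if patches is not None else {}
    return pd.DataFrame(
        {
            "id": ids.astype(int),
            "type": [types.get(int(i), "") for i in ids],
            "cells": counts.astype(int),
            "area_km2": counts * spec.cell_area_km2(),
        }
    )


def patches_to_geojson(patches: PatchSet, path: str | Path | None = None) -> dict:
    obj = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(p.geometry),
                "properties": {"id": p.id, "type": p.type},
            }
            for p in patches
        ],
    }
    if path is not None:
        Path(path).write_text(json.dumps(obj))
    return obj


def patches_from_geojson(source: str | Path | dict) -> PatchSet:
    if not isinstance(source, dict):
        source = json.loads(Path(source).read_text())
    return PatchSet(
        patches=[
            Patch(
                id=int(f["properties"]["id"]),
                type=str(f["properties"]["type"]),
                geometry=shape(f["geometry"]),
            )
            for f in source["features"]
        ]
    )
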