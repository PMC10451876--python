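"""End-to-end orchestration: patches -> resistance -> network -> corridors
-> pinch points, with every intermediate written to disk and a JSON report.

A run is driven by a :class:`PipelineConfig` (constructed in code, from a
YAML file, or by the CLI). Inputs are either file paths (DEM and land-use
``.asc`` rasters, patches GeoJSON) or a synthetic-scene preset; outputs are
plain-text rasters, CSV tables and a ``report.json`` carrying parameters,
seeds and the package version for provenance. Reruns with the same config
are bit-identical.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import circuit, corridors, pinchpoints, resistance, synthetic
from .grid import Raster, points_from_geojson, points_to_geojson, read_asc, write_asc
from .patches import (
    PatchSet,
    patch_areas,
    patches_from_geojson,
    patches_to_geojson,
    rasterize_patches,
)


class PipelineStageError(RuntimeError):
    """An error in a named pipeline stage; wraps the offending input."""


@dataclass
class PipelineConfig:
    """Parameters of one pipeline run (defaults mirror the study design:
    8-neighborhood, ten corridor classes with the top two kept, three pinch
    levels inside a 10 km type-I buffer)."""

    out_dir: str = "ecocircuit_run"
    seed: int = 0
    # either a synthetic preset ...
    preset: str | None = None  # "channel" | "mosaic"
    nrows: int = 100
    ncols: int = 100
    cell_size: float = 1000.0
    # ... or explicit inputs
    dem_path: str | None = None
    landuse_path: str | None = None
    patches_path: str | None = None
    points_path: str | None = None
    classification_path: str | None = None
    # stage parameters
    cap: float | None = None
    neighborhood: int = 8
    sources_type: str | None = None
    corridor_k: int = 10
    corridor_top_classes: int = 2
    corridor_threshold: float | None = None
    pinch_k: int = 3
    buffer_radius_m: float = 10_000.0
    n_warning_points: int = 200
    tolerance_cells: int = 2
    n_null: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineStageError(f"stage config: unknown fields {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.preset is None:
            for name in ("dem_path", "landuse_path", "patches_path"):
                value = getattr(self, name)
                if value is None:
                    raise PipelineStageError(
                        f"stage config: no preset and missing required field {name}"
                    )
                if not Path(value).exists():
                    raise PipelineStageError(
                        f"stage config: {name} does not exist: {value}"
                    )
        elif self.preset not in ("channel", "mosaic"):
            raise PipelineStageError(
                f"stage config: preset must be channel or mosaic, got {self.preset}"
            )


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as err:
                raise PipelineStageError(f"stage {name}: {err}") from err
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in order and return the summary report (also written
    as ``report.json`` under ``config.out_dir``)."""
    from . import __version__

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config": asdict(config),
        "stages": {},
    }
    t0 = time.time()

    # --- inputs ---------------------------------------------------------
    scene = None
    points = None
    if config.preset is not None:
        maker = synthetic.channel_scene if config.preset == "channel" else synthetic.mosaic_scene
        scene = _stage("inputs")(maker)(
            seed=config.seed, nrows=config.nrows, ncols=config.ncols,
            cell_size=config.cell_size,
        )
        dem, landuse, patches = scene.dem, scene.landuse, scene.patches
    else:
        dem = _stage("inputs")(read_asc)(config.dem_path)
        landuse = _stage("inputs")(read_asc)(config.landuse_path, dtype=int)
        patches = _stage("inputs")(patches_from_geojson)(config.patches_path)
        if config.points_path:
            points = _stage("inputs")(points_from_geojson)(config.points_path)
    rc = _stage("inputs")(resistance.load_classification)(config.classification_path)

    # --- patches --------------------------------------------------------
    labels = _stage("patches")(rasterize_patches)(patches, dem.spec)
    areas = patch_areas(labels, patches)
    report["stages"]["patches"] = {
        "n_patches": len(patches),
        "total_area_km2": float(areas["area_km2"].sum()),
    }

    # --- resistance -----------------------------------------------------
    combined, factors = _stage("resistance")(resistance.build_resistance_surface)(
        dem, landuse, config=rc, cap=config.cap
    )
    vals = combined.valid_values
    report["stages"]["resistance"] = {
        "min": float(vals.min()), "max": float(vals.max()),
        "mean": float(vals.mean()),
    }

    # --- network --------------------------------------------------------
    graph = _stage("network")(circuit.build_graph)(
        combined, labels, neighborhood=config.neighborhood
    )
    current = _stage("network")(circuit.accumulate_current)(
        graph, patches, sources_type=config.sources_type
    )
    report["stages"]["network"] = {
        "n_nodes": graph.n_nodes,
        "n_pairs_solved": current.n_pairs,
        "unreachable_pairs": current.unreachable_pairs,
        "reff": {
            f"{a}-{b}": float(current.reff.loc[a, b])
            for i, a in enumerate(current.reff.index)
            for b in current.reff.columns[i + 1 :]
        },
    }

    if points is None:
        points = _stage("network")(synthetic.generate_warning_points)(
            current.raster, n=config.n_warning_points, seed=config.seed + 1000
        )

    # --- corridors ------------------------------------------------------
    corridor = _stage("corridors")(corridors.extract_corridors)(
        current, k=config.corridor_k, top_classes=config.corridor_top_classes,
        patch_labels=labels, threshold=config.corridor_threshold,
    )
    corridor.composition = corridors.zonal_composition(corridor.mask, landuse, config=rc)
    report["stages"]["corridors"] = {
        "n_groups": corridor.n_groups,
        "n_cells": corridor.n_cells,
        "area_km2": corridor.area_km2,
        "threshold_used": corridor.threshold_used,
        "breaks": corridor.jenks.breaks.tolist() if corridor.jenks else None,
        "forest_grassland_percent": _fg_percent(corridor.composition),
    }

    # --- pinch points ---------------------------------------------------
    buffer = _stage("pinch_points")(pinchpoints.buffer_patches)(
        patches, labels, radius_m=config.buffer_radius_m
    )
    pinch = _stage("pinch_points")(pinchpoints.extract_pinch_points)(
        current, buffer, k=config.pinch_k, patch_labels=labels,
        landuse=landuse, config=rc, buffer_radius_m=config.buffer_radius_m,
    )
    validation = _stage("pinch_points")(pinchpoints.validate_points)(
        pinch, points, tolerance_cells=config.tolerance_cells,
        n_null=config.n_null, seed=config.seed + 2000,
    )
    report["stages"]["pinch_points"] = {
        "n_cells": pinch.n_cells,
        "total_area_km2": pinch.total_area_km2,
        "forest_grassland_percent": _fg_percent(pinch.composition),
        "validation": validation,
    }
    # --- outputs --------------------------------------------------------
    write_asc(dem, out / "dem.asc")
    write_asc(landuse, out / "landuse.asc")
    write_asc(combined, out / "resistance.asc")
    write_asc(labels, out / "patch_labels.asc")
    write_asc(current.raster, out / "current.asc")
    write_asc(Raster(corridor.mask.values.astype(int), dem.spec), out / "corridors.asc")
    write_asc(Raster(pinch.mask.values.astype(int), dem.spec), out / "pinch_points.asc")
    patches_to_geojson(patches, out / "patches.geojson")
    points_to_geojson(points, out / "warning_points.geojson")
    areas.to_csv(out / "patch_areas.csv", index=False)
    current.reff.to_csv(out / "reff.csv")
    corridor.composition.to_csv(out / "corridor_composition.csv", index=False)
    if pinch.composition is not None:
        pinch.composition.to_csv(out / "pinch_composition.csv", index=False)
    (out / "report.json").write_text(json.dumps(report, indent=2, default=_jsonify))
    (out / "config.yaml").write_text(yaml.safe_dump(asdict(config)))
    report["elapsed_s"] = round(time.time() - t0, 3)  # not written: reruns stay bit-identical
    return report


def _fg_percent(composition) -> float | None:
    if composition is None or composition.empty:
        return None
    row = composition[composition["group"] == "forest_grassland_total"]
    return float(row["percent"].iloc[0]) if len(row) else None


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
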