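"""Corridor extraction: Jenks natural breaks, thresholding, zonal statistics.

The cumulative current map is classified into ``k`` ordered categories with
the Jenks natural-breaks method (exact Fisher dynamic programming), and the
top ``top_classes`` categories — the highest current densities, i.e. the
highest passage probabilities — form the corridor mask. Land-use composition
of the mask is reported by zonal statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .circuit import CurrentMap
from .grid import Raster
from .resistance import FOREST_GRASS_CODES, ResistanceConfig


class JenksError(ValueError):
    """Classification infeasible (fewer distinct values than classes)."""


class EmptyCorridorError(ValueError):
    """No positive current anywhere; nothing to classify."""


@dataclass
class JenksBreaks:
    """Result of a Jenks natural-breaks classification.

    ``breaks`` are the k-1 ascending class upper bounds (data values: the
    maximum of classes 1..k-1). ``gvf`` is the goodness-of-variance fit,
    1 - SSD_within / SSD_total.
    """

    k: int
    breaks: np.ndarray
    gvf: float
    n: int
    n_used: int
    subsampled: bool = False

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Class index 1..k for each value (<= break i -> class <= i)."""
        return np.searchsorted(self.breaks, np.asarray(values), side="left") + 1


def _jenks_dp(x: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Exact Fisher–Jenks DP on sorted data; returns break indices and SSD."""
    n = x.size
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def seg_cost(i: np.ndarray, j: int) -> np.ndarray:
        # within-class sum of squared deviations of x[i:j]
        cnt = j - i
        s = s1[j] - s1[i]
        return (s2[j] - s2[i]) - s * s / cnt

    big = np.inf
    cost = np.full((k + 1, n + 1), big)
    back = np.zeros((k + 1, n + 1), dtype=int)
    idx_all = np.arange(n + 1)
    cnt = np.arange(1, n + 1)
    cost[1, 1:] = s2[1:] - s1[1:] ** 2 / cnt
    for m in range(2, k + 1):
        for j in range(m, n + 1):
            i = idx_all[m - 1 : j]
            cand = cost[m - 1, i] + seg_cost(i, j)
            best = int(np.argmin(cand))
            cost[m, j] = cand[best]
            back[m, j] = i[best]
    # recover class boundaries
    bounds = np.zeros(k + 1, dtype=int)
    bounds[k] = n
    for m in range(k, 1, -1):
        bounds[m - 1] = back[m, bounds[m]]
    return bounds, float(cost[k, n])


def jenks_breaks(values, k: int, max_exact_n: int = 2000) -> JenksBreaks:
    """Jenks natural-breaks classification of a 1-D sample into k classes.

    The exact dynamic-programming optimum (minimum total within-class sum of
    squared deviations) is computed when the sample has at most
    ``max_exact_n`` values; larger samples are reduced to a deterministic
    stratified subsample (evenly spaced order statistics of the sorted data,
    endpoints always included) before the exact algorithm runs. The
    subsampling is recorded in the result.
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = x.size
    if k < 2:
        raise JenksError(f"need at least 2 classes, got k={k}")
    if np.unique(x).size < k:
        raise JenksError(
            f"need at least {k} distinct values for {k} classes, "
            f"got {np.unique(x).size}"
        )
    subsampled = n > max_exact_n
    if subsampled:
        idx = np.unique(np.round(np.linspace(0, n - 1, max_exact_n)).astype(int))
        xs = x[idx]
        if np.unique(xs).size < k:  # extremely skewed sample: keep all distinct
            xs = np.unique(x)
    else:
        xs = x
    bounds, ssd = _jenks_dp(xs, k)
    breaks = xs[bounds[1:k] - 1]  # max value of classes 1..k-1
    total = float(((xs - xs.mean()) ** 2).sum())
    gvf = 1.0 - ssd / total if total > 0 else 1.0
    return JenksBreaks(
        k=k, breaks=breaks, gvf=gvf, n=n, n_used=xs.size, subsampled=subsampled
    )


@dataclass
class CorridorMask:
    """Corridor cells (boolean raster) with threshold and diagnostics."""

    mask: Raster
    threshold_used: float
    jenks: JenksBreaks
    n_groups: int
    composition: pd.DataFrame | None = None

    @property
    def n_cells(self) -> int:
        return int(self.mask.values.sum())

    @property
    def area_km2(self) -> float:
        return self.n_cells * self.mask.spec.cell_area_km2()


def extract_corridors(
    current: CurrentMap | Raster,
    k: int = 10,
    top_classes: int = 2,
    exclude_patches: bool = True,
    patch_labels: Raster | None = None,
    threshold: float | None = None,
    max_exact_n: int = 2000,
) -> CorridorMask:
    """Corridor mask = cells in the top ``top_classes`` of ``k`` Jenks
    classes of positive current density.

    Classification runs on positive-current cells only; focal-patch
    interiors are excluded when ``exclude_patches`` and ``patch_labels`` are
    given (their terminal throughput is not corridor). An absolute
    ``threshold`` overrides the Jenks-derived cut entirely. Corridor groups
    are 8-connected components of the mask.
    """
    raster = current.raster if isinstance(current, CurrentMap) else current
    values = raster.values
    eligible = raster.mask & (values > 0)
    if exclude_patches and patch_labels is not None:
        eligible &= patch_labels.values == 0
    if not eligible.any():
        raise EmptyCorridorError("current map has no positive cells to classify")

    if threshold is not None:
        jenks = None
        corridor = eligible & (values >= threshold)
        threshold_used = float(threshold)
    else:
        if not 1 <= top_classes <= k:
            raise JenksError(f"top_classes must be in 1..{k}, got {top_classes}")
        jenks = jenks_breaks(values[eligible], k, max_exact_n=max_exact_n)
        classes = jenks.assign(values[eligible])
        corridor = np.zeros_like(eligible)
        corridor[eligible] = classes > k - top_classes
        threshold_used = float(values[corridor].min()) if corridor.any() else np.nan

    structure = np.ones((3, 3), dtype=int)  # 8-connectivity
    _, n_groups = ndimage.label(corridor, structure=structure)
    return CorridorMask(
        mask=Raster(corridor, raster.spec),
        threshold_used=threshold_used,
        jenks=jenks,
        n_groups=int(n_groups),
    )


def zonal_composition(
    mask: Raster | np.ndarray,
    landuse: Raster,
    config: ResistanceConfig | None = None,
) -> pd.DataFrame:
    """Land-use composition of a boolean zone mask.

    One row per land-use code present in the zone (cells, km^2, percent of
    zone area), plus an aggregate row for the forest+grassland group
    (woodland + grassland codes). Percentages over the code rows sum to 100.
    """
    if isinstance(mask, Raster):
        mask.same_grid(landuse)
        m = mask.values.astype(bool)
    else:
        m = np.asarray(mask, dtype=bool)
    m = m & landuse.mask
    spec = landuse.spec
    if not m.any():
        warnings.warn("zonal composition of an empty mask", stacklevel=2)
        return pd.DataFrame(
            columns=["code", "group", "cells", "area_km2", "percent"]
        )
    codes, counts = np.unique(landuse.values[m].astype(int), return_counts=True)
    total = counts.sum()
    groups = [config.group_of_code(int(c)) if config is not None else "" for c in codes]
    df = pd.DataFrame(
        {
            "code": codes,
            "group": groups,
            "cells": counts,
            "area_km2": counts * spec.cell_area_km2(),
            "percent": 100.0 * counts / total,
        }
    )
    fg = df["code"].isin(FOREST_GRASS_CODES)
    agg = pd.DataFrame(
        {
            "code": [-1],
            "group": ["forest_grassland_total"],
            "cells": [int(df.loc[fg, "cells"].sum())],
            "area_km2": [float(df.loc[fg, "area_km2"].sum())],
            "percent": [float(df.loc[fg, "percent"].sum())],
        }
    )
    return pd.concat([df, agg], ignore_index=True)
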