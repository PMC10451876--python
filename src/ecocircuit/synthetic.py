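"""Seeded synthetic study areas for exercising the full pipeline.

Real inputs for this kind of analysis (a DEM, a categorical land-use raster,
reserve polygons, observation points) are heavy and restricted; this module
generates small planar stand-ins with the statistical structure the pipeline
assumes: a spatially autocorrelated DEM, a contiguous land-use mosaic
covering all five resistance groups, disjoint near-circular habitat patches
of types I and II, and observation points drawn from a current-density map.
All generators are pure functions of (grid, parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import Point, box

from .grid import GridSpec, Raster
from .patches import Patch, PatchSet
from .resistance import ResistanceConfig, load_classification


class ConfigurationError(ValueError):
    pass


class PlacementError(RuntimeError):
    """Rejection sampling could not place a patch without overlap."""


class SamplingError(ValueError):
    """Point sampling from an all-zero density map."""


#: Default land-use group mixture for the mosaic preset: a shrub/grass and
#: forest dominated landscape with scattered wet/agricultural and built-up
#: areas, loosely in the spirit of a south-Yunnan mosaic.
DEFAULT_CLASS_WEIGHTS = {
    "shrub_grass": 0.30,
    "forest_dry": 0.35,
    "swamp_beach_rural": 0.10,
    "otherwood_paddy_rock": 0.15,
    "urban_water": 0.10,
}


@dataclass
class SyntheticScene:
    """One synthetic study area: all rasters share a single GridSpec."""

    spec: GridSpec
    dem: Raster
    landuse: Raster
    patches: PatchSet
    seed: int
    warning_points: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    channel_mask: np.ndarray | None = None  # planted corridor (channel preset)
    pinch_cols: tuple[int, int] | None = None  # constriction column range


def _smooth_field(spec: GridSpec, smoothness: float, rng) -> np.ndarray:
    noise = rng.standard_normal(spec.shape)
    return ndimage.gaussian_filter(noise, sigma=smoothness, mode="reflect")


def generate_dem(
    spec: GridSpec,
    relief: float = 1000.0,
    base_elevation: float = 500.0,
    smoothness: float = 10.0,
    seed: int = 0,
) -> Raster:
    """Smooth random-field DEM in [base_elevation, base_elevation + relief].

    ``smoothness`` is the Gaussian correlation length in cells; larger
    values give monotonically stronger spatial autocorrelation. ``relief=0``
    returns a flat surface.
    """
    if relief < 0:
        raise ConfigurationError(f"relief must be >= 0, got {relief}")
    if smoothness < 1:
        raise ConfigurationError(f"smoothness must be >= 1, got {smoothness}")
    rng = np.random.default_rng(seed)
    f = _smooth_field(spec, smoothness, rng)
    if relief == 0 or np.ptp(f) == 0:
        return Raster(np.full(spec.shape, float(base_elevation)), spec)
    z = base_elevation + relief * (f - f.min()) / np.ptp(f)
    return Raster(z, spec)


def generate_landuse(
    spec: GridSpec,
    dem: Raster | None = None,
    class_weights: dict[str, float] | None = None,
    seed: int = 0,
    smoothness: float = 8.0,
    dem_weight: float = 0.0,
    config: ResistanceConfig | None = None,
) -> Raster:
    """Contiguous land-use mosaic covering the five resistance groups.

    A smooth random field is thresholded at the cumulative quantiles of
    ``class_weights`` (group -> areal share, summing to 1), so empirical
    group frequencies track the weights closely. Within each group, codes
    from the group's code list are laid out by a second smooth field, giving
    blobby sub-mosaics rather than salt-and-pepper codes. ``dem_weight`` > 0
    mixes standardized elevation into the group field (higher ground leans
    toward later groups).
    """
    if config is None:
        config = load_classification()
    groups = config.landuse_groups
    if class_weights is None:
        class_weights = DEFAULT_CLASS_WEIGHTS
    unknown = set(class_weights) - set(groups)
    if unknown:
        raise ConfigurationError(f"unknown land-use groups: {sorted(unknown)}")
    total = sum(class_weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"class_weights must sum to 1, got {total}")

    rng = np.random.default_rng(seed)
    f = _smooth_field(spec, smoothness, rng)
    if dem_weight and dem is not None:
        z = (dem.values - dem.values.mean()) / (dem.values.std() or 1.0)
        fz = (f - f.mean()) / (f.std() or 1.0)
        f = (1 - dem_weight) * fz + dem_weight * z
    sub = _smooth_field(spec, max(smoothness / 2, 1.0), rng)

    names = [g for g in groups if class_weights.get(g, 0.0) > 0]
    weights = np.array([class_weights[g] for g in names])
    # quantile thresholds on the realized field -> near-exact areal shares
    qs = np.cumsum(weights)[:-1]
    cuts = np.quantile(f, qs) if len(qs) else np.array([])
    group_idx = np.searchsorted(cuts, f, side="right")

    codes = np.zeros(spec.shape, dtype=int)
    for gi, name in enumerate(names):
        cells = group_idx == gi
        if not cells.any():
            continue
        group_codes = groups[name]["codes"]
        ncodes = len(group_codes)
        sub_cuts = np.quantile(sub[cells], np.arange(1, ncodes) / ncodes)
        codes[cells] = np.asarray(group_codes)[
            np.searchsorted(sub_cuts, sub[cells], side="right")
        ]
    return Raster(codes, spec)


def generate_patches(
    spec: GridSpec,
    n_type1: int = 1,
    n_type2: int = 1,
    radius_cells: int = 4,
    seed: int = 0,
    max_attempts: int = 1000,
    min_gap_cells: float = 3.0,
) -> PatchSet:
    """Disjoint near-circular patches by seeded rejection sampling.

    The first ``n_type1`` patches are type I. Centers keep at least
    ``min_gap_cells`` between patch rims (so patches stay non-adjacent on
    the grid) and a margin from the border. Raises :class:`PlacementError`
    naming the first patch that cannot be placed.
    """
    if n_type1 < 1:
        raise ConfigurationError("need at least one type-I patch")
    n_total = n_type1 + n_type2
    patch_area = n_total * np.pi * radius_cells**2
    if patch_area >= 0.25 * spec.n_cells:
        raise PlacementError(
            f"{n_total} patches of radius {radius_cells} would cover "
            f">=25% of the grid; infeasible"
        )
    rng = np.random.default_rng(seed)
    cell = spec.cell_size
    margin = radius_cells + 2
    centers: list[tuple[float, float]] = []
    patches: list[Patch] = []
    for i in range(n_total):
        ptype = "I" if i < n_type1 else "II"
        for _ in range(max_attempts):
            row = rng.uniform(margin, spec.nrows - margin)
            col = rng.uniform(margin, spec.ncols - margin)
            if all(
                np.hypot(row - r0, col - c0) >= 2 * radius_cells + min_gap_cells
                for r0, c0 in centers
            ):
                centers.append((row, col))
                x, y = spec.cell_center(row - 0.5, col - 0.5)
                patches.append(
                    Patch(id=i + 1, type=ptype,
                          geometry=Point(float(x), float(y)).buffer(radius_cells * cell))
                )
                break
        else:
            raise PlacementError(
                f"could not place patch {i + 1} (type {ptype}) after "
                f"{max_attempts} attempts"
            )
    return PatchSet(patches=patches)


def generate_warning_points(
    current: Raster, n: int, seed: int = 0, jitter: bool = True
) -> np.ndarray:
    """``n`` points sampled with probability proportional to cell current
    density; planar (x, y) coordinates, jittered within the cell."""
    vals = np.where(current.mask, np.maximum(current.values, 0.0), 0.0)
    total = vals.sum()
    if (vals < 0).any() or not np.isfinite(total):
        raise SamplingError("current map must be non-negative and finite")
    if total <= 0:
        raise SamplingError("all-zero current map; cannot sample points")
    rng = np.random.default_rng(seed)
    flat = rng.choice(vals.size, size=n, p=vals.ravel() / total)
    rows, cols = np.unravel_index(flat, current.spec.shape)
    x, y = current.spec.cell_center(rows, cols)
    if jitter:
        cell = current.spec.cell_size
        x = x + rng.uniform(-0.5, 0.5, size=n) * cell
        y = y + rng.uniform(-0.5, 0.5, size=n) * cell
    return np.column_stack([x, y])


def mosaic_scene(
    seed: int = 0,
    nrows: int = 100,
    ncols: int = 100,
    cell_size: float = 1000.0,
    relief: float = 2500.0,
    base_elevation: float = 600.0,
    n_type1: int = 1,
    n_type2: int = 2,
    radius_cells: int = 4,
) -> SyntheticScene:
    """General-purpose scene: autocorrelated DEM spanning all elevation
    classes, elevation-correlated land-use mosaic, and disjoint patches."""
    spec = GridSpec(nrows=nrows, ncols=ncols, cell_size=cell_size)
    dem = generate_dem(spec, relief=relief, base_elevation=base_elevation,
                       smoothness=12.0, seed=seed)
    landuse = generate_landuse(spec, dem=dem, seed=seed + 1, dem_weight=0.3)
    patches = generate_patches(spec, n_type1=n_type1, n_type2=n_type2,
                               radius_cells=radius_cells, seed=seed + 2)
    return SyntheticScene(spec=spec, dem=dem, landuse=landuse, patches=patches,
                          seed=seed)


def channel_scene(
    seed: int = 0,
    nrows: int = 100,
    ncols: int = 100,
    cell_size: float = 1000.0,
    pinch_cols: tuple[int, int] = (37, 46),
    plateau_elevation: float = 2150.0,
    plateau_relief: float = 600.0,
    valley_elevation: float = 700.0,
) -> SyntheticScene:
    """The canonical planted-structure fixture: a mountain-pass landscape.

    Two square patches (type I left, type II right) occupy flat valley
    floors in a high, rugged plateau, connected by a single low-resistance
    shrub valley. The valley is an hourglass: a one-cell-wide pass over
    ``pinch_cols`` flush with the type-I patch face (inside its 10 km
    buffer) opens through short diagonal stairs into twin one-cell-wide
    branches that rejoin the type-II patch. Every segment is a series path,
    so the channel's current densities form exactly two tight clusters —
    the branches at half the injected current and the pass at the full
    current — with no intermediate values; the pass is both the narrowest
    cross-section and the current maximum, i.e. the planted pinch point.

    The plateau sits mostly above the top elevation class and its steep
    valley walls fall into the top slope and roughness classes, so the
    matrix is strongly resistive on terrain grounds alone — the regime the
    resistance model describes (high, steep ground blocks movement; gentle
    low valleys carry it). Real cumulative current maps are multi-scale:
    many routes of graded quality sit below the best corridor, and a
    ten-class corridor scheme presumes that structure. Three secondary
    valley routes of graded quality (shrub paths degraded by woodland/paddy
    cells) provide a discrete ladder of currents well below the channel's,
    and a low-elevation mosaic shelf along the southern edge — fed through
    two long degraded access valleys — adds the smooth fat-tailed diffuse
    background. ``channel_mask`` marks the planted channel cells and
    ``pinch_cols`` the pass columns.
    """
    if nrows < 80 or ncols < 90:
        raise ConfigurationError("channel scene needs at least 80x90 cells")
    spec = GridSpec(nrows=nrows, ncols=ncols, cell_size=cell_size)

    rng = np.random.default_rng(seed)
    f = _smooth_field(spec, 5.0, rng)
    f = (f - f.min()) / (np.ptp(f) or 1.0)  # [0, 1]
    plateau = plateau_elevation - plateau_relief / 2 + plateau_relief * f

    matrix_weights = {
        "urban_water": 0.40,
        "otherwood_paddy_rock": 0.25,
        "swamp_beach_rural": 0.20,
        "forest_dry": 0.15,
    }
    landuse = generate_landuse(spec, class_weights=matrix_weights, seed=seed + 1)
    lu = landuse.values.copy()

    mid = nrows // 2
    half = 3  # patch half-height/width in cells
    left_cols = (ncols // 4 + 5, ncols // 4 + 11)
    right_cols = (left_cols[1] + 20, left_cols[1] + 26)

    def _box(col_lo: int, col_hi: int):
        x0, y0 = spec.origin
        return box(
            x0 + col_lo * cell_size,
            y0 - (mid + half + 1) * cell_size,
            x0 + (col_hi + 1) * cell_size,
            y0 - (mid - half) * cell_size,
        )

    patches = PatchSet(
        patches=[
            Patch(id=1, type="I", geometry=_box(*left_cols)),
            Patch(id=2, type="II", geometry=_box(*right_cols)),
        ]
    )
    from .patches import rasterize_patches  # local import avoids cycle at top

    labels = rasterize_patches(patches, spec).values

    c0, c1 = left_cols[1] + 1, right_cols[0] - 1
    pc0, pc1 = pinch_cols
    channel = np.zeros(spec.shape, dtype=bool)
    channel[mid, pc0 : pc1 + 1] = True  # single-width pass: the pinch
    for sgn in (-1, 1):
        for k in range(1, half + 1):    # diagonal stairs out of the pass
            channel[mid + sgn * k, pc1 + k] = True
        channel[mid + sgn * half, pc1 + half + 1 : c1 + 1] = True  # twin branches
    channel &= labels == 0

    # Seven nested U-shaped secondary valley routes of graded quality:
    # shrub paths degraded by a rising count of woodland/paddy cells, so
    # their (series) currents ladder evenly below the channel's. Shallower
    # routes use inner face columns, deeper routes outer ones, so no two
    # routes cross. Together with the background they give the cumulative
    # current map the multi-scale structure of real landscapes.
    detours: list[tuple[np.ndarray, int | None]] = []

    def _route(row_off: int, vc_off: int, n_degrade: int) -> None:
        vcl = left_cols[1] - vc_off
        vcr = right_cols[0] + vc_off
        row = mid + row_off
        m = np.zeros(spec.shape, dtype=bool)
        if row_off < 0:
            m[row + 1 : mid - half, vcl] = True
            m[row + 1 : mid - half, vcr] = True
        else:
            m[mid + half + 1 : row, vcl] = True
            m[mid + half + 1 : row, vcr] = True
        m[row, vcl : vcr + 1] = True
        m &= labels == 0
        detours.append((m, 22))
        if n_degrade > 0:
            rr, cc = np.nonzero(m)
            order = np.lexsort((rr, cc))  # along the path, left to right
            pick = np.round(np.linspace(2, order.size - 3, n_degrade)).astype(int)
            d = np.zeros(spec.shape, dtype=bool)
            d[rr[order[pick]], cc[order[pick]]] = True
            detours.append((d, 24))

    _route(-8, 0, 3)
    _route(+8, 0, 5)
    _route(-14, 2, 6)

    # A diffuse low-elevation shelf along the southern edge, reached from
    # each patch through a long degraded access valley. The shelf's mosaic
    # carries a small share of the flow spread smoothly over thousands of
    # cells — the fat-tailed diffuse background that real cumulative current
    # maps always show below their discrete corridors.
    shelf_top = nrows - 22
    shelf = np.zeros(spec.shape, dtype=bool)
    shelf[shelf_top:, :] = True
    shelf_dem = 800.0 + 250.0 * f[shelf]

    access = np.zeros(spec.shape, dtype=bool)
    for col in (left_cols[0] + 2, right_cols[1] - 2):
        access[mid + half + 1 : shelf_top + 1, col] = True
    access &= labels == 0
    rr, cc = np.nonzero(access)
    order = np.lexsort((rr, cc))
    pick = np.round(np.linspace(2, order.size - 3, 20)).astype(int)
    degrade = np.zeros_like(access)
    degrade[rr[order[pick]], cc[order[pick]]] = True
    detours.append((access & ~degrade, 22))
    detours.append((access & degrade, 24))

    # carve flat valley floors: structures plus a one-cell apron, so every
    # structure cell has an all-valley 3x3 window (zero slope), while apron
    # cells see the plateau and land in the top slope/roughness classes
    eight = np.ones((3, 3), dtype=bool)
    structures = channel | (labels > 0)
    for m, _ in detours:
        structures |= m
    valley = ndimage.binary_dilation(structures, structure=eight) & ~shelf
    dem_vals = np.where(valley, valley_elevation, plateau)
    dem_vals[shelf] = shelf_dem
    dem = Raster(dem_vals, spec)

    lu[valley & ~structures] = 51  # urban apron along the valley walls
    for m, code in detours:
        lu[m & ~channel & ~shelf] = code
    lu[channel] = 22      # shrubbery channel
    lu[labels > 0] = 22   # low-resistance patch interiors
    lu[2:4, 2:4] = 31     # token grassland corner: all five groups present
    landuse = Raster(lu, spec)

    return SyntheticScene(
        spec=spec, dem=dem, landuse=landuse, patches=patches, seed=seed,
        channel_mask=channel, pinch_cols=pinch_cols,
    )
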