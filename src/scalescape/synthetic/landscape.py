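"""Generator for managed-boreal harvest-mosaic landscapes.

Emulates the structure of a rasterized vegetation inventory at 5 m grain:
a matrix of mature upland stands (conifer / deciduous / mixedwood), lowland
pockets, harvest blocks binned into 10-year regeneration age classes with
optional retention islands, and wide vegetated linear features (pipelines,
wellsite access) crossing the mosaic. Block outlines are rectangles perturbed
by smoothed random noise, so a single *shape-complexity* knob moves the
landscape from straight conventional cutblock edges toward the irregular
boundaries of natural-disturbance-emulation forestry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ..raster import ClassRaster, ClassTable, DEFAULT_NODATA

__all__ = [
    "LandscapeParams",
    "build_class_table",
    "generate_landscape",
    "place_sites",
    "REGEN_CODES",
    "MATURE_CODES",
    "LINEAR_CODE",
    "LOWLAND_CODES",
]

MATURE_CONIFER = 1
MATURE_DECID = 2
MATURE_MIXED = 3
MATURE_CODES = (MATURE_CONIFER, MATURE_DECID, MATURE_MIXED)

# regenerating harvest, 10-year age bins for the first eight decades
REGEN_CODES = tuple(range(10, 18))

LINEAR_CODE = 30
LOWLAND_FOREST = 40
LOWLAND_OPEN = 41
LOWLAND_CODES = (LOWLAND_FOREST, LOWLAND_OPEN)

_AGE_LABELS = {
    MATURE_CONIFER: "120+",
    MATURE_DECID: "120+",
    MATURE_MIXED: "80-119",
    LINEAR_CODE: None,
    LOWLAND_FOREST: "120+",
    LOWLAND_OPEN: None,
}


def build_class_table() -> ClassTable:
    """Class semantics for generated landscapes (code, vegetation, age, flags)."""
    rows = [
        (MATURE_CONIFER, "white_spruce", "120+", True, True),
        (MATURE_DECID, "aspen", "120+", True, True),
        (MATURE_MIXED, "mixedwood", "80-119", True, True),
    ]
    for i, code in enumerate(REGEN_CODES):
        rows.append((code, "regen_harvest", f"{10 * i}-{10 * i + 9}", True, True))
    rows.append((LINEAR_CODE, "grass_shrub_linear", None, True, True))
    rows.append((LOWLAND_FOREST, "black_spruce_lowland", "120+", False, True))
    rows.append((LOWLAND_OPEN, "open_fen", None, False, True))
    df = pd.DataFrame(
        rows, columns=["class_code", "vegetation", "age_class", "upland", "vegetated"]
    )
    return ClassTable(df)


@dataclass
class LandscapeParams:
    """Knobs of the mosaic generator; defaults give a realistic managed mosaic.

    Sizes are in cells/ha/metres as named. ``shape_complexity`` in [0, 1]
    controls boundary perturbation amplitude of harvest blocks (0 = clean
    rectangles). ``pad_m`` keeps blocks away from the raster edge so circular
    buffers up to that radius fit around any in-block survey point.
    """

    shape: tuple[int, int] = (2000, 2000)
    cell_size: float = 5.0
    matrix_mix: dict[int, float] = field(
        default_factory=lambda: {MATURE_CONIFER: 0.4, MATURE_DECID: 0.4, MATURE_MIXED: 0.2}
    )
    n_matrix_seeds: int = 120
    n_blocks: int = 200
    block_area_ha_mean: float = 11.0  # harvest areas 7 ha upward, mean 11 ha
    block_area_ha_sd: float = 6.0  # long right tail: sizes are lognormal
    block_area_ha_min: float = 7.0
    block_overlap_tolerance: float = 0.15  # touching blocks form harvest complexes
    block_age_decades: tuple[int, ...] = (0, 1)  # first two decades of regeneration
    shape_complexity: float = 0.5
    retention_fraction: float = 0.05
    n_linear_features: int = 8
    linear_width_m: float = 10.0
    lowland_fraction: float = 0.10
    pad_m: float = 520.0
    nodata: int = DEFAULT_NODATA

    def __post_init__(self) -> None:
        if not 0 <= self.retention_fraction <= 1:
            raise ValueError("retention_fraction must be in [0, 1]")
        if not 0 <= self.lowland_fraction <= 1:
            raise ValueError("lowland_fraction must be in [0, 1]")
        if not 0 <= self.shape_complexity <= 1:
            raise ValueError("shape_complexity must be in [0, 1]")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.block_area_ha_min * 10_000 < self.cell_size**2:
            raise ValueError("blocks must cover at least one cell")


def _smooth_field(shape: tuple[int, int], sigma: float, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(shape).astype(np.float32)
    f = ndimage.gaussian_filter(noise, sigma=sigma)
    return (f - f.mean()) / (f.std() + 1e-12)


def _block_mask(
    area_cells: float, complexity: float, rng: np.random.Generator
) -> np.ndarray:
    """A harvest-block footprint: a rectangle with noise-perturbed boundary."""
    aspect = rng.uniform(0.75, 1.3)
    half_h = max(int(round(np.sqrt(area_cells * aspect) / 2)), 1)
    half_w = max(int(round(np.sqrt(area_cells / aspect) / 2)), 1)
    margin = max(int(4 + 10 * complexity), 4)
    win = (2 * (half_h + margin) + 1, 2 * (half_w + margin) + 1)
    rect = np.zeros(win, dtype=bool)
    cy, cx = win[0] // 2, win[1] // 2
    rect[cy - half_h : cy + half_h + 1, cx - half_w : cx + half_w + 1] = True
    if complexity <= 0:
        return rect
    # signed distance to the rectangle boundary, positive inside
    sdf = ndimage.distance_transform_edt(rect) - ndimage.distance_transform_edt(~rect)
    noise = _smooth_field(win, sigma=3.0, rng=rng)
    amp = complexity * 0.45 * min(half_h, half_w)
    mask = (sdf + amp * noise) > 0
    if not mask.any():
        return rect
    # keep the largest connected component so the block stays one patch
    lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    sizes = np.bincount(lab.ravel())[1:]
    return lab == (int(np.argmax(sizes)) + 1)


def generate_landscape(
    params: LandscapeParams, seed: int
) -> tuple[ClassRaster, ClassTable]:
    """Generate a mosaic landscape; deterministic given ``params`` and ``seed``."""
    rng = np.random.default_rng(seed)
    nrow, ncol = params.shape
    h = params.cell_size
    grid = np.empty((nrow, ncol), dtype=np.int32)

    # --- mature matrix: nearest-seed (Voronoi) tessellation of matrix classes
    codes = np.array(sorted(params.matrix_mix))
    probs = np.array([params.matrix_mix[c] for c in codes], dtype=float)
    probs = probs / probs.sum()
    n_seeds = max(params.n_matrix_seeds, len(codes))
    seed_r = rng.integers(0, nrow, n_seeds)
    seed_c = rng.integers(0, ncol, n_seeds)
    seed_class = rng.choice(codes, size=n_seeds, p=probs)
    seed_mask = np.ones((nrow, ncol), dtype=bool)
    seed_mask[seed_r, seed_c] = False
    _, (ir, ic) = ndimage.distance_transform_edt(seed_mask, return_indices=True)
    seed_id = np.full((nrow, ncol), -1, dtype=np.int64)
    seed_id[seed_r, seed_c] = np.arange(n_seeds)
    grid[:] = seed_class[seed_id[ir, ic]]

    # --- lowlands: smoothed-noise blobs covering ~lowland_fraction of the grid
    if params.lowland_fraction > 0:
        sigma_low = min(min(nrow, ncol) / 18, 60)
        low_field = _smooth_field((nrow, ncol), sigma=sigma_low, rng=rng)
        thr = np.quantile(low_field, params.lowland_fraction)
        lowland = low_field < thr
        split = _smooth_field((nrow, ncol), sigma=sigma_low / 2, rng=rng)
        grid[lowland & (split >= 0)] = LOWLAND_FOREST
        grid[lowland & (split < 0)] = LOWLAND_OPEN

    # --- harvest blocks (painted over upland only; harvest avoids lowlands)
    pad_cells = int(np.ceil(params.pad_m / h))
    cell_ha = h * h / 10_000.0
    # lognormal block sizes: mean ~ block_area_ha_mean with a long right tail,
    # the shape of real cutblock size registries
    mu = np.log(params.block_area_ha_mean**2 /
                np.sqrt(params.block_area_ha_mean**2 + params.block_area_ha_sd**2))
    sig = np.sqrt(np.log1p((params.block_area_ha_sd / params.block_area_ha_mean) ** 2))
    areas_ha = np.maximum(
        rng.lognormal(mu, sig, params.n_blocks), params.block_area_ha_min
    )
    total_block_cells = areas_ha.sum() / cell_ha
    usable = max(nrow - 2 * pad_cells, 0) * max(ncol - 2 * pad_cells, 0)
    if total_block_cells > 0.5 * usable or usable == 0:
        raise ValueError(
            f"infeasible packing: {areas_ha.sum():.0f} ha of blocks into "
            f"{usable * cell_ha:.0f} ha of usable grid"
        )
    harvest_any = np.zeros((nrow, ncol), dtype=bool)
    upland_matrix = np.isin(grid, codes)
    for area_ha in areas_ha:
        mask = _block_mask(area_ha / cell_ha, params.shape_complexity, rng)
        mh, mw = mask.shape
        if mh + 2 * pad_cells >= nrow or mw + 2 * pad_cells >= ncol:
            raise ValueError("infeasible packing: block larger than usable grid")
        placed = False
        for _ in range(200):
            r0 = int(rng.integers(pad_cells, nrow - pad_cells - mh))
            c0 = int(rng.integers(pad_cells, ncol - pad_cells - mw))
            window = harvest_any[r0 : r0 + mh, c0 : c0 + mw]
            if (window & mask).sum() <= params.block_overlap_tolerance * mask.sum():
                decade = int(rng.choice(params.block_age_decades))
                code = REGEN_CODES[decade]
                target = grid[r0 : r0 + mh, c0 : c0 + mw]
                paint = mask & upland_matrix[r0 : r0 + mh, c0 : c0 + mw]
                target[paint] = code
                window |= paint
                placed = True
                break
        if not placed:
            raise ValueError(
                "infeasible packing: could not place a harvest block after 200 tries"
            )

    # --- retention islands: mature cells left standing inside blocks
    if params.retention_fraction > 0 and harvest_any.any():
        ret_field = _smooth_field((nrow, ncol), sigma=4.0, rng=rng)
        thr = np.quantile(ret_field[harvest_any], 1.0 - params.retention_fraction)
        retention = harvest_any & (ret_field > thr)
        ret_class = rng.choice(codes, size=int(retention.sum()), p=probs)
        grid[retention] = ret_class

    # --- wide linear features: straight strips crossing the whole mosaic
    if params.n_linear_features > 0 and params.linear_width_m > 0:
        yy, xx = np.mgrid[0:nrow, 0:ncol]
        half_w_cells = max(params.linear_width_m / h, 1.0) / 2.0
        for _ in range(params.n_linear_features):
            theta = rng.uniform(0, np.pi)
            py, px = rng.uniform(0, nrow), rng.uniform(0, ncol)
            d = np.abs(np.cos(theta) * (yy - py) - np.sin(theta) * (xx - px))
            grid[d <= half_w_cells] = LINEAR_CODE

    raster = ClassRaster(grid=grid, cell_size=h, origin=(0.0, 0.0), nodata=params.nodata)
    return raster, build_class_table()


def place_sites(
    landscape: ClassRaster,
    n: int,
    min_spacing: float = 300.0,
    edge_clearance: float = 150.0,
    seed: int = 0,
    max_attempts_per_site: int = 400,
) -> pd.DataFrame:
    """Place survey sites inside harvest blocks.

    Sites satisfy pairwise spacing >= ``min_spacing`` (m) and distance to the
    harvest-area edge >= ``edge_clearance`` (m). Retention islands and linear
    features punched *through* a block are interior to the harvest area, so
    clearance is measured on the morphologically closed harvest footprint
    (but a site cell itself is always a harvest cell). Rejection sampling
    with a bounded budget; an unsatisfiable configuration raises an error
    reporting how many sites were achieved.
    """
    rng = np.random.default_rng(seed)
    harvest = np.isin(landscape.grid, REGEN_CODES)
    if not harvest.any():
        raise ValueError("landscape has no harvest cells")
    h = landscape.cell_size
    closed = ndimage.binary_closing(
        harvest, structure=np.ones((15, 15), dtype=bool), iterations=1
    )
    interior_dist = ndimage.distance_transform_edt(closed) * h
    candidates = np.argwhere((interior_dist >= edge_clearance) & harvest)
    if len(candidates) == 0:
        raise ValueError(
            f"no harvest cell is {edge_clearance} m clear of block edges: "
            "edge_clearance exceeds every block's interior radius"
        )
    x0, y0 = landscape.origin
    placed: list[tuple[float, float]] = []
    # greedy pass over the shuffled candidate list: near-maximal packing,
    # deterministic given the seed
    order = rng.permutation(len(candidates))
    budget = min(len(order), max_attempts_per_site * n)
    for k in order[:budget]:
        if len(placed) >= n:
            break
        r, c = candidates[k]
        x = x0 + (c + 0.5) * h
        y = y0 + (r + 0.5) * h
        if all((x - px) ** 2 + (y - py) ** 2 >= min_spacing**2 for px, py in placed):
            placed.append((x, y))
    if len(placed) < n:
        raise ValueError(
            f"could not place {n} sites with spacing {min_spacing} m and "
            f"clearance {edge_clearance} m; achieved {len(placed)}"
        )
    return pd.DataFrame(
        {
            "site": [f"S{i + 1:03d}" for i in range(n)],
            "x": [p[0] for p in placed],
            "y": [p[1] for p in placed],
        }
    )
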