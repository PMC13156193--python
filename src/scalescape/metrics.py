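"""Landscape-level configuration metrics evaluated inside circular buffers.

Five FRAGSTATS-style landscape-level indices — edge density (m/ha), Shannon
diversity (SHDI), contagion (CONTAG, %), perimeter–area fractal dimension
(PAFRAC), and the coefficient of variation of the core area index (CAI CV, %)
— plus the proportion of upland cover used as a productivity covariate.

Metrics that cannot be computed on a given buffer (a single class for CONTAG,
fewer than 10 patches or a degenerate regression for PAFRAC, zero mean core
index for CAI CV) come back as *undefined values with a reason*, never as
exceptions: sparse buffers are data, and downstream model scans skip them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import (
    CircularExtent,
    ClassRaster,
    ClassTable,
    PatchGeometry,
    clip_circular,
    delineate_patches,
    patch_geometry,
)

__all__ = [
    "MetricValue",
    "ClassComposition",
    "AdjacencyTally",
    "class_composition",
    "adjacency_tally",
    "edge_density",
    "shannon_diversity",
    "contagion",
    "pafrac",
    "cai_cv",
    "proportion_uplands",
    "metric_scan",
    "METRIC_NAMES",
]

METRIC_NAMES = ("edge_density", "shdi", "contag", "pafrac", "cai_cv")

PAFRAC_MIN_PATCHES = 10  # below this the perimeter-area regression is unreliable


@dataclass(frozen=True)
class MetricValue:
    """A metric evaluated on one buffer; ``defined=False`` carries the reason."""

    metric: str
    value: float | None
    defined: bool = True
    reason: str | None = None
    n_patches: int = 0
    extent: CircularExtent | None = None

    def __post_init__(self) -> None:
        if self.defined and self.value is None:
            raise ValueError("defined metric must carry a value")
        if not self.defined and self.value is not None:
            raise ValueError("undefined metric must not carry a value")


def _undefined(metric: str, reason: str, n_patches: int = 0) -> MetricValue:
    return MetricValue(metric, None, defined=False, reason=reason, n_patches=n_patches)


@dataclass(frozen=True)
class ClassComposition:
    """Distinct classes and their proportions of non-nodata area."""

    codes: np.ndarray
    proportions: np.ndarray

    @property
    def m(self) -> int:
        return len(self.codes)


def class_composition(raster: ClassRaster) -> ClassComposition:
    vals = raster.grid[raster.data_mask]
    if vals.size == 0:
        raise ValueError("raster has no data cells")
    codes, counts = np.unique(vals, return_counts=True)
    return ClassComposition(codes=codes, proportions=counts / vals.size)


@dataclass(frozen=True)
class AdjacencyTally:
    """Cell-face adjacency counts g_ik between classes, double-count convention.

    Each internal face between two data cells is tallied once from each side,
    so the matrix is symmetric with even diagonal entries. Faces adjoining
    nodata or the grid boundary are excluded.
    """

    codes: np.ndarray
    g: np.ndarray  # shape (m, m)


def adjacency_tally(raster: ClassRaster) -> AdjacencyTally:
    comp = class_composition(raster)
    codes = comp.codes  # sorted by np.unique
    m = len(codes)
    g = np.zeros((m, m), dtype=np.int64)
    grid = raster.grid
    mask = raster.data_mask
    # horizontal and vertical internal face pairs
    for a, b, ma, mb in (
        (grid[:, :-1], grid[:, 1:], mask[:, :-1], mask[:, 1:]),
        (grid[:-1, :], grid[1:, :], mask[:-1, :], mask[1:, :]),
    ):
        ok = ma & mb
        ia = np.searchsorted(codes, a[ok])
        ib = np.searchsorted(codes, b[ok])
        np.add.at(g, (ia, ib), 1)
        np.add.at(g, (ib, ia), 1)
    return AdjacencyTally(codes=codes, g=g)


def edge_density(raster: ClassRaster) -> MetricValue:
    """Total length of between-class internal faces per unit data area (m/ha).

    Faces adjoining nodata or the clipped buffer boundary carry no edge: the
    artificial circle outline never contributes to edge density.
    """
    mask = raster.data_mask
    n_data = int(mask.sum())
    if n_data == 0:
        raise ValueError("raster has no data cells")
    grid = raster.grid
    edges = 0
    for a, b, ma, mb in (
        (grid[:, :-1], grid[:, 1:], mask[:, :-1], mask[:, 1:]),
        (grid[:-1, :], grid[1:, :], mask[:-1, :], mask[1:, :]),
    ):
        ok = ma & mb
        edges += int(np.count_nonzero((a != b) & ok))
    length_m = edges * raster.cell_size
    area_ha = n_data * raster.cell_size**2 / 10_000.0
    return MetricValue("edge_density", length_m / area_ha)


def shannon_diversity(raster: ClassRaster) -> MetricValue:
    """SHDI = −Σ P_i ln P_i over class proportions of non-nodata area."""
    comp = class_composition(raster)
    p = comp.proportions
    return MetricValue("shdi", float(-(p * np.log(p)).sum()))


def contagion(raster: ClassRaster) -> MetricValue:
    """CONTAG (%) — entropy-based aggregation of class adjacencies, in (0, 100].

    CONTAG = 100 · [1 + Σ_i Σ_k q_ik ln q_ik / (2 ln m)] with
    q_ik = P_i · g_ik / Σ_k g_ik. Undefined when fewer than two classes are
    present. Zero terms (q_ik = 0, or a class with no tallied adjacencies)
    contribute nothing, by the q ln q → 0 limit.
    """
    comp = class_composition(raster)
    if comp.m < 2:
        return _undefined("contag", "fewer than 2 classes")
    tally = adjacency_tally(raster)
    g = tally.g.astype(float)
    row_sums = g.sum(axis=1)
    q = np.zeros_like(g)
    nonzero = row_sums > 0
    q[nonzero] = comp.proportions[nonzero, None] * g[nonzero] / row_sums[nonzero, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(q > 0, q * np.log(q), 0.0)
    value = 100.0 * (1.0 + terms.sum() / (2.0 * np.log(comp.m)))
    return MetricValue("contag", float(value))


def pafrac(geometry: PatchGeometry) -> MetricValue:
    """Perimeter–area fractal dimension: 2 / slope of ln(area m²) on ln(perimeter m).

    1 for self-similar simple shapes, toward 2 for highly convoluted ones.
    Undefined with fewer than 10 patches, or when all perimeters are equal
    (zero regressor variance).
    """
    n = geometry.n_patches
    if n < PAFRAC_MIN_PATCHES:
        reason = f"requires at least {PAFRAC_MIN_PATCHES} patches, got {n}"
        return _undefined("pafrac", reason, n_patches=n)
    ln_p = np.log(geometry.perimeter_m)
    ln_a = np.log(geometry.area_ha * 10_000.0)
    sxx = float(((ln_p - ln_p.mean()) ** 2).sum())
    if sxx < 1e-12:
        return _undefined("pafrac", "zero perimeter variance", n_patches=n)
    slope = float(((ln_p - ln_p.mean()) * (ln_a - ln_a.mean())).sum()) / sxx
    if abs(slope) < 1e-12:
        return _undefined("pafrac", "zero regression slope", n_patches=n)
    return MetricValue("pafrac", 2.0 / slope, n_patches=n)


def cai_cv(geometry: PatchGeometry) -> MetricValue:
    """Coefficient of variation (%) of the per-patch core area index.

    CAI = 100 · core/area per patch; CV = 100 · population SD / mean.
    Undefined when the mean CAI is zero (every patch entirely edge).
    """
    n = geometry.n_patches
    if n == 0:
        raise ValueError("patch geometry is empty")
    cai = 100.0 * geometry.core_area_ha / geometry.area_ha
    mean = float(cai.mean())
    if mean <= 0:
        return _undefined("cai_cv", "mean core area index is zero", n_patches=n)
    sd = float(cai.std(ddof=0))  # population SD, the FRAGSTATS CV convention
    return MetricValue("cai_cv", 100.0 * sd / mean, n_patches=n)


def proportion_uplands(raster: ClassRaster, table: ClassTable) -> float:
    """Fraction of non-nodata cells carrying an upland-flagged class."""
    mask = raster.data_mask
    n_data = int(mask.sum())
    if n_data == 0:
        raise ValueError("raster has no data cells")
    upland = np.isin(raster.grid, sorted(table.upland_codes()))
    return float(np.count_nonzero(upland & mask)) / n_data


def compute_all_metrics(
    clipped: ClassRaster,
    table: ClassTable | None = None,
    *,
    connectivity: int = 8,
    edge_depth_m: float | None = None,
    metrics: tuple[str, ...] = METRIC_NAMES,
) -> dict[str, MetricValue]:
    """Configuration metrics (all five by default) on an already-clipped buffer."""
    unknown = set(metrics) - set(METRIC_NAMES)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    if edge_depth_m is None:
        edge_depth_m = clipped.cell_size
    out: dict[str, MetricValue] = {}
    patches = delineate_patches(clipped, connectivity=connectivity)
    n = patches.n_patches
    geom = None
    if {"pafrac", "cai_cv"} & set(metrics):
        geom = patch_geometry(patches, edge_depth_m=edge_depth_m)
    if "edge_density" in metrics:
        out["edge_density"] = MetricValue(
            "edge_density", edge_density(clipped).value, n_patches=n
        )
    if "shdi" in metrics:
        out["shdi"] = MetricValue(
            "shdi", shannon_diversity(clipped).value, n_patches=n
        )
    if "contag" in metrics:
        out["contag"] = contagion(clipped)
    if "pafrac" in metrics:
        out["pafrac"] = pafrac(geom)
    if "cai_cv" in metrics:
        out["cai_cv"] = cai_cv(geom)
    return out


def metric_scan(
    raster: ClassRaster,
    center: tuple[float, float],
    radii: np.ndarray | list[float],
    table: ClassTable | None = None,
    *,
    connectivity: int = 8,
    edge_depth_m: float | None = None,
    site: str | int | None = None,
    metrics: tuple[str, ...] = METRIC_NAMES,
) -> pd.DataFrame:
    """Evaluate configuration metrics at every buffer radius around a point.

    Returns a long-format frame with one row per (metric, radius):
    ``site, metric, radius_m, extent_ha, value, defined, reason, n_patches``.
    When a class table is supplied, a ``prop_upland`` row is added per radius.
    """
    radii = np.asarray(radii, dtype=float)
    if radii.size == 0:
        raise ValueError("radius schedule is empty")
    if np.any(np.diff(radii) <= 0):
        raise ValueError("radius schedule must be strictly increasing")
    rows = []
    for r in radii:
        extent = CircularExtent(center=center, radius=float(r))
        clipped = clip_circular(raster, extent)
        values = compute_all_metrics(
            clipped, table, connectivity=connectivity, edge_depth_m=edge_depth_m,
            metrics=metrics,
        )
        for name in metrics:
            mv = values[name]
            rows.append(
                {
                    "site": site,
                    "metric": name,
                    "radius_m": float(r),
                    "extent_ha": extent.area_ha,
                    "value": mv.value if mv.defined else np.nan,
                    "defined": mv.defined,
                    "reason": mv.reason,
                    "n_patches": mv.n_patches,
                }
            )
        if table is not None:
            rows.append(
                {
                    "site": site,
                    "metric": "prop_upland",
                    "radius_m": float(r),
                    "extent_ha": extent.area_ha,
                    "value": proportion_uplands(clipped, table),
                    "defined": True,
                    "reason": None,
                    "n_patches": next(iter(values.values())).n_patches,
                }
            )
    return pd.DataFrame(rows)
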