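"""Independent naive implementations used as oracles by the test suite.

Everything here is written with explicit per-cell loops and textbook formulas,
deliberately sharing no code with the package implementation. Only intended
for small grids (<= ~50x50).
"""

from __future__ import annotations

import math

import numpy as np


def naive_cells_in_circle(
    nrow: int, ncol: int, cell: float, origin, cx: float, cy: float, radius: float
) -> int:
    """Brute-force count of cells whose centre lies strictly inside the circle."""
    x0, y0 = origin
    count = 0
    for r in range(nrow):
        for c in range(ncol):
            x = x0 + (c + 0.5) * cell
            y = y0 + (r + 0.5) * cell
            if (x - cx) ** 2 + (y - cy) ** 2 < radius**2:
                count += 1
    return count


def naive_patches(grid: np.ndarray, nodata: int, connectivity: int):
    """Flood-fill patch labelling; returns (labels, patch_class list)."""
    nrow, ncol = grid.shape
    labels = np.zeros((nrow, ncol), dtype=int)
    patch_class = []
    if connectivity == 4:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        neigh = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    next_label = 0
    for r in range(nrow):
        for c in range(ncol):
            if grid[r, c] == nodata or labels[r, c] != 0:
                continue
            next_label += 1
            code = grid[r, c]
            patch_class.append(int(code))
            stack = [(r, c)]
            labels[r, c] = next_label
            while stack:
                rr, cc = stack.pop()
                for dr, dc in neigh:
                    r2, c2 = rr + dr, cc + dc
                    if (
                        0 <= r2 < nrow
                        and 0 <= c2 < ncol
                        and labels[r2, c2] == 0
                        and grid[r2, c2] == code
                    ):
                        labels[r2, c2] = next_label
                        stack.append((r2, c2))
    return labels, patch_class


def naive_patch_geometry(grid, labels, n_patches, nodata, cell, depth_cells):
    """Per-patch area (ha), perimeter (m), core area (ha) by per-cell loops."""
    nrow, ncol = grid.shape
    cell_ha = cell * cell / 10_000.0
    area = np.zeros(n_patches)
    perim = np.zeros(n_patches)
    core = np.zeros(n_patches)
    for r in range(nrow):
        for c in range(ncol):
            lab = labels[r, c]
            if lab == 0:
                continue
            area[lab - 1] += cell_ha
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                r2, c2 = r + dr, c + dc
                if not (0 <= r2 < nrow and 0 <= c2 < ncol):
                    perim[lab - 1] += cell
                elif labels[r2, c2] != lab:
                    perim[lab - 1] += cell
            if depth_cells == 0:
                core[lab - 1] += cell_ha
            else:
                # core cell: every cell within Chebyshev distance depth shares the class
                is_core = True
                code = grid[r, c]
                for dr in range(-depth_cells, depth_cells + 1):
                    for dc in range(-depth_cells, depth_cells + 1):
                        r2, c2 = r + dr, c + dc
                        if not (0 <= r2 < nrow and 0 <= c2 < ncol):
                            is_core = False
                        elif grid[r2, c2] != code:
                            is_core = False
                if is_core:
                    core[lab - 1] += cell_ha
    return area, perim, core


def naive_edge_density(grid: np.ndarray, nodata: int, cell: float) -> float:
    nrow, ncol = grid.shape
    edge_m = 0.0
    n_data = 0
    for r in range(nrow):
        for c in range(ncol):
            if grid[r, c] == nodata:
                continue
            n_data += 1
            for dr, dc in ((0, 1), (1, 0)):  # each internal face once
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < nrow and 0 <= c2 < ncol:
                    if grid[r2, c2] != nodata and grid[r2, c2] != grid[r, c]:
                        edge_m += cell
    return edge_m / (n_data * cell * cell / 10_000.0)


def naive_proportions(grid: np.ndarray, nodata: int):
    counts: dict[int, int] = {}
    for v in grid.ravel():
        if v == nodata:
            continue
        counts[int(v)] = counts.get(int(v), 0) + 1
    total = sum(counts.values())
    return {k: v / total for k, v in sorted(counts.items())}


def naive_shdi(grid: np.ndarray, nodata: int) -> float:
    props = naive_proportions(grid, nodata)
    return -sum(p * math.log(p) for p in props.values())


def naive_contag(grid: np.ndarray, nodata: int):
    """Explicit CONTAG formula; None when < 2 classes."""
    props = naive_proportions(grid, nodata)
    codes = sorted(props)
    m = len(codes)
    if m < 2:
        return None
    idx = {c: i for i, c in enumerate(codes)}
    g = np.zeros((m, m))
    nrow, ncol = grid.shape
    for r in range(nrow):
        for c in range(ncol):
            if grid[r, c] == nodata:
                continue
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):  # both directions
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < nrow and 0 <= c2 < ncol and grid[r2, c2] != nodata:
                    g[idx[int(grid[r, c])], idx[int(grid[r2, c2])]] += 1
    total = 0.0
    for i, ci in enumerate(codes):
        row_sum = g[i].sum()
        if row_sum == 0:
            continue
        for k in range(m):
            q = props[ci] * g[i, k] / row_sum
            if q > 0:
                total += q * math.log(q)
    return 100.0 * (1.0 + total / (2.0 * math.log(m)))


def naive_pafrac(area_ha, perim_m, min_patches=10):
    """2 / OLS slope of ln(area m2) on ln(perimeter m); None when undefined."""
    n = len(area_ha)
    if n < min_patches:
        return None
    x = [math.log(p) for p in perim_m]
    yv = [math.log(a * 10_000.0) for a in area_ha]
    mx = sum(x) / n
    my = sum(yv) / n
    sxx = sum((xi - mx) ** 2 for xi in x)
    if sxx < 1e-12:
        return None
    slope = sum((xi - mx) * (yi - my) for xi, yi in zip(x, yv)) / sxx
    if abs(slope) < 1e-12:
        return None
    return 2.0 / slope


def naive_cai_cv(area_ha, core_ha):
    cai = [100.0 * c / a for a, c in zip(area_ha, core_ha)]
    n = len(cai)
    mean = sum(cai) / n
    if mean <= 0:
        return None
    var = sum((v - mean) ** 2 for v in cai) / n  # population variance
    return 100.0 * math.sqrt(var) / mean


def naive_all_metrics(grid: np.ndarray, nodata: int, cell: float, depth_cells: int = 1):
    """All five metrics by the naive route (8-connectivity patches)."""
    labels, patch_class = naive_patches(grid, nodata, connectivity=8)
    area, perim, core = naive_patch_geometry(
        grid, labels, len(patch_class), nodata, cell, depth_cells
    )
    return {
        "edge_density": naive_edge_density(grid, nodata, cell),
        "shdi": naive_shdi(grid, nodata),
        "contag": naive_contag(grid, nodata),
        "pafrac": naive_pafrac(area, perim),
        "cai_cv": naive_cai_cv(area, core),
    }


def random_grid(rng: np.random.Generator, nodata: int = -9999):
    """A random categorical grid <= 50x50 with occasional nodata holes."""
    nrow = int(rng.integers(4, 51))
    ncol = int(rng.integers(4, 51))
    n_classes = int(rng.integers(1, 6))
    # mix of speckle and blobs for a range of aggregation levels
    grid = rng.integers(1, n_classes + 1, size=(nrow, ncol)).astype(np.int32)
    for _ in range(int(rng.integers(0, 4))):
        r0, c0 = int(rng.integers(0, nrow)), int(rng.integers(0, ncol))
        hh, ww = int(rng.integers(1, nrow // 2 + 1)), int(rng.integers(1, ncol // 2 + 1))
        grid[r0 : r0 + hh, c0 : c0 + ww] = int(rng.integers(1, n_classes + 1))
    if rng.random() < 0.3:
        hole = rng.random((nrow, ncol)) < 0.1
        grid[hole] = nodata
        if (grid != nodata).sum() == 0:
            grid[0, 0] = 1
    return grid
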