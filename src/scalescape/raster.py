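"""Categorical raster container, file I/O, circular clipping and patch geometry.

The landscape is a square-celled categorical grid (integer class codes) in a
continuous metric coordinate system. Grid indexing is 0-based row-major with
the origin at the lower-left corner: row 0 is the southernmost row, and the
centre of cell ``(r, c)`` sits at ``origin + ((c + 0.5) h, (r + 0.5) h)`` for
cell side ``h``. ESRI ASCII grids and GeoTIFFs store rows north-first, so the
readers/writers flip row order at the file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ClassRaster",
    "ClassTable",
    "CircularExtent",
    "PatchSet",
    "PatchGeometry",
    "read_class_raster",
    "read_class_table",
    "write_class_raster",
    "clip_circular",
    "delineate_patches",
    "patch_geometry",
]

DEFAULT_NODATA = -9999

CLASS_TABLE_COLUMNS = ["class_code", "vegetation", "age_class", "upland", "vegetated"]


class RasterFormatError(ValueError):
    """Raised when a raster file cannot be interpreted as an integer grid."""


class RasterValidationError(ValueError):
    """Raised when raster contents violate the class-table contract."""


@dataclass(frozen=True)
class CircularExtent:
    """A circular buffer: centre in metres plus radius in metres."""

    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")

    @property
    def area_ha(self) -> float:
        return np.pi * self.radius**2 / 10_000.0


def radius_for_area_ha(area_ha: float) -> float:
    """Radius (m) of the disc with the given area in hectares."""
    return float(np.sqrt(area_ha * 10_000.0 / np.pi))


@dataclass
class ClassRaster:
    """2-D integer class-code grid with square cells in metric coordinates."""

    grid: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: int = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise RasterFormatError(
                f"class raster must hold integers, got dtype {self.grid.dtype}"
            )
        if self.grid.ndim != 2 or self.grid.size == 0:
            raise ValueError("grid must be 2-D with at least one cell")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in metres."""
        nrow, ncol = self.grid.shape
        x0, y0 = self.origin
        return (x0, y0, x0 + ncol * self.cell_size, y0 + nrow * self.cell_size)

    @property
    def data_mask(self) -> np.ndarray:
        return self.grid != self.nodata

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of cell centres, shaped like the grid."""
        nrow, ncol = self.grid.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncol) + 0.5) * self.cell_size
        ys = y0 + (np.arange(nrow) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def classes_present(self) -> np.ndarray:
        vals = np.unique(self.grid)
        return vals[vals != self.nodata]

    def copy(self) -> "ClassRaster":
        return replace(self, grid=self.grid.copy())


@dataclass
class ClassTable:
    """Semantics of class codes: vegetation label, age class, upland flag."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CLASS_TABLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"class table missing columns: {missing}")
        if self.df["class_code"].duplicated().any():
            dups = self.df.loc[self.df["class_code"].duplicated(), "class_code"]
            raise ValueError(f"duplicate class codes: {sorted(set(dups))}")
        self.df = self.df.reset_index(drop=True)

    @property
    def codes(self) -> set[int]:
        return set(int(c) for c in self.df["class_code"])

    def upland_codes(self) -> set[int]:
        sel = self.df["upland"].astype(bool)
        return set(int(c) for c in self.df.loc[sel, "class_code"])

    def validate_raster(self, raster: ClassRaster) -> None:
        present = set(int(c) for c in raster.classes_present())
        unknown = sorted(present - self.codes)
        if unknown:
            raise RasterValidationError(
                f"raster codes absent from class table: {unknown}"
            )
        if raster.nodata in self.codes:
            raise RasterValidationError(
                f"nodata code {raster.nodata} must not appear in the class table"
            )


def read_class_table(path: str | Path) -> ClassTable:
    df = pd.read_csv(path)
    for col in ("upland", "vegetated"):
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col].astype(str).str.strip().str.lower().isin(
                {"true", "1", "yes", "t"}
            )
    return ClassTable(df)


def write_class_table(table: ClassTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# File formats: ESRI ASCII grid and single-band integer GeoTIFF
# ---------------------------------------------------------------------------

def _read_ascii_grid(path: Path) -> ClassRaster:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise RasterFormatError(f"ASCII grid missing header field {key}")
    body = " ".join(lines[i:])
    values = body.split()
    try:
        arr = np.array([int(v) for v in values])
    except ValueError as exc:
        raise RasterFormatError(f"non-integer cell value in {path}: {exc}") from exc
    nrow, ncol = int(header["nrows"]), int(header["ncols"])
    if arr.size != nrow * ncol:
        raise RasterFormatError(
            f"expected {nrow * ncol} cells, found {arr.size} in {path}"
        )
    grid = arr.reshape(nrow, ncol)[::-1]  # file is north-first; row 0 = south
    return ClassRaster(
        grid=grid.astype(np.int32),
        cell_size=float(header["cellsize"]),
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
        nodata=int(header.get("nodata_value", DEFAULT_NODATA)),
    )


def _write_ascii_grid(raster: ClassRaster, path: Path) -> None:
    nrow, ncol = raster.grid.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncol}\n")
        fh.write(f"nrows {nrow}\n")
        fh.write(f"xllcorner {raster.origin[0]:.6f}\n")
        fh.write(f"yllcorner {raster.origin[1]:.6f}\n")
        fh.write(f"cellsize {raster.cell_size:.6f}\n")
        fh.write(f"NODATA_value {raster.nodata}\n")
        for row in raster.grid[::-1]:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def _read_geotiff(path: Path) -> ClassRaster:
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        if arr.ndim == 3 and arr.shape[-1] == 1:
            arr = arr[..., 0]
        if arr.ndim != 2:
            raise RasterFormatError("multi-band rasters are not supported")
        if not np.issubdtype(arr.dtype, np.integer):
            raise RasterFormatError(
                f"GeoTIFF band must be integer, got dtype {arr.dtype}"
            )
        tags = page.tags
        cell_size = 1.0
        origin = (0.0, 0.0)
        nodata = DEFAULT_NODATA
        if _TAG_MODEL_PIXEL_SCALE in tags:
            sx, sy = tags[_TAG_MODEL_PIXEL_SCALE].value[:2]
            cell_size = float(sx)
        if _TAG_MODEL_TIEPOINT in tags:
            tp = tags[_TAG_MODEL_TIEPOINT].value
            # tiepoint maps raster (0,0) = top-left corner to world (X, Y)
            top_left_x, top_left_y = float(tp[3]), float(tp[4])
            origin = (top_left_x, top_left_y - arr.shape[0] * cell_size)
        if _TAG_GDAL_NODATA in tags:
            nodata = int(float(tags[_TAG_GDAL_NODATA].value))
    grid = arr[::-1].astype(np.int32)  # TIFF rows are north-first
    return ClassRaster(grid=grid, cell_size=cell_size, origin=origin, nodata=nodata)


def _write_geotiff(raster: ClassRaster, path: Path) -> None:
    import tifffile

    nrow = raster.grid.shape[0]
    top_left_y = raster.origin[1] + nrow * raster.cell_size
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (raster.cell_size, raster.cell_size, 0.0)),
        (
            _TAG_MODEL_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, raster.origin[0], top_left_y, 0.0),
        ),
        (_TAG_GDAL_NODATA, "s", 0, str(raster.nodata)),
    ]
    tifffile.imwrite(
        str(path), raster.grid[::-1].astype(np.int32), extratags=extratags
    )


def read_class_raster(
    raster_path: str | Path, class_table_path: str | Path | None = None
) -> tuple[ClassRaster, ClassTable | None]:
    """Read a categorical raster (GeoTIFF or ESRI ASCII grid) and its class table.

    When a class table path is given, every non-nodata code in the raster is
    validated against it; a code with no table row raises
    :class:`RasterValidationError` naming the offending codes.
    """
    raster_path = Path(raster_path)
    suffix = raster_path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        raster = _read_geotiff(raster_path)
    elif suffix in {".asc", ".txt", ".grd"}:
        raster = _read_ascii_grid(raster_path)
    else:
        # sniff: TIFF magic bytes, else assume ASCII
        with open(raster_path, "rb") as fh:
            magic = fh.read(4)
        if magic[:2] in (b"II", b"MM"):
            raster = _read_geotiff(raster_path)
        else:
            raster = _read_ascii_grid(raster_path)
    table = None
    if class_table_path is not None:
        table = read_class_table(class_table_path)
        table.validate_raster(raster)
    return raster, table


def write_class_raster(raster: ClassRaster, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        _write_geotiff(raster, path)
    else:
        _write_ascii_grid(raster, path)


# ---------------------------------------------------------------------------
# Circular clipping
# ---------------------------------------------------------------------------

def clip_circular(raster: ClassRaster, extent: CircularExtent) -> ClassRaster:
    """Clip a raster to a circular buffer.

    A cell is retained iff its centre lies strictly within ``extent.radius`` of
    the centre point (the dominant raster-GIS convention); all other cells are
    set to nodata and the grid is cropped to the buffer's bounding square.
    Raises if the buffer's bounding square extends past the raster edge, so
    synthetic landscapes must be generated with padding around survey points.
    """
    cx, cy = extent.center
    xmin, ymin, xmax, ymax = raster.bounds
    if not (xmin <= cx <= xmax and ymin <= cy <= ymax):
        raise ValueError(f"buffer centre {extent.center} outside raster bounds")
    r = extent.radius
    if cx - r < xmin or cx + r > xmax or cy - r < ymin or cy + r > ymax:
        raise ValueError(
            f"buffer (centre {extent.center}, radius {r} m) extends beyond the "
            "raster edge; generate landscapes with padding"
        )
    h = raster.cell_size
    x0, y0 = raster.origin
    nrow, ncol = raster.grid.shape
    c_lo = max(int(np.floor((cx - r - x0) / h)), 0)
    c_hi = min(int(np.ceil((cx + r - x0) / h)), ncol)
    r_lo = max(int(np.floor((cy - r - y0) / h)), 0)
    r_hi = min(int(np.ceil((cy + r - y0) / h)), nrow)
    sub = raster.grid[r_lo:r_hi, c_lo:c_hi].copy()
    xs = x0 + (np.arange(c_lo, c_hi) + 0.5) * h
    ys = y0 + (np.arange(r_lo, r_hi) + 0.5) * h
    dx = xs[None, :] - cx
    dy = ys[:, None] - cy
    outside = dx * dx + dy * dy >= r * r
    sub[outside] = raster.nodata
    return ClassRaster(
        grid=sub,
        cell_size=h,
        origin=(x0 + c_lo * h, y0 + r_lo * h),
        nodata=raster.nodata,
    )


# ---------------------------------------------------------------------------
# Patch delineation and geometry
# ---------------------------------------------------------------------------

_STRUCT_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT_8 = np.ones((3, 3), dtype=bool)


@dataclass
class PatchSet:
    """Connected same-class components of a categorical raster.

    ``labels`` assigns 1..n_patches to data cells (0 = nodata); ``patch_class``
    maps patch id (1-based) to its class code.
    """

    labels: np.ndarray
    patch_class: np.ndarray  # length n_patches, class code of each patch
    connectivity: int
    cell_size: float
    nodata: int = DEFAULT_NODATA

    @property
    def n_patches(self) -> int:
        return len(self.patch_class)


def delineate_patches(raster: ClassRaster, connectivity: int = 8) -> PatchSet:
    """Label maximal connected same-class components (FRAGSTATS patch rule).

    Connectivity 8 (queen's case, the FRAGSTATS default) joins diagonal
    neighbours of the same class into one patch; connectivity 4 does not.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if not raster.data_mask.any():
        raise ValueError("raster has no data cells to delineate")
    structure = _STRUCT_8 if connectivity == 8 else _STRUCT_4
    labels = np.zeros(raster.grid.shape, dtype=np.int32)
    patch_class: list[int] = []
    offset = 0
    for code in raster.classes_present():
        mask = raster.grid == code
        lab, n = ndimage.label(mask, structure=structure)
        labels[mask] = lab[mask] + offset
        patch_class.extend([int(code)] * n)
        offset += n
    return PatchSet(
        labels=labels,
        patch_class=np.asarray(patch_class, dtype=np.int64),
        connectivity=connectivity,
        cell_size=raster.cell_size,
        nodata=raster.nodata,
    )


@dataclass
class PatchGeometry:
    """Per-patch area (ha), perimeter (m) and core area (ha) at a fixed edge depth."""

    area_ha: np.ndarray
    perimeter_m: np.ndarray
    core_area_ha: np.ndarray
    edge_depth_m: float
    patch_class: np.ndarray = field(default=None)

    @property
    def n_patches(self) -> int:
        return len(self.area_ha)


def _face_count_per_patch(labels: np.ndarray, n_patches: int) -> np.ndarray:
    """Cell faces of each patch adjoining a different label, nodata, or the grid edge."""
    counts = np.zeros(n_patches + 1, dtype=np.int64)
    padded = np.pad(labels, 1, constant_values=0)
    center = padded[1:-1, 1:-1]
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        neigh = padded[1 + dr : padded.shape[0] - 1 + dr,
                       1 + dc : padded.shape[1] - 1 + dc]
        diff = (center != neigh) & (center > 0)
        counts += np.bincount(center[diff], minlength=n_patches + 1)
    return counts[1:]


def patch_geometry(patches: PatchSet, edge_depth_m: float = 0.0) -> PatchGeometry:
    """Compute area, perimeter and core area for every patch.

    Perimeter counts all cell faces adjoining a different class, nodata, or the
    (possibly clipped) grid boundary. Core area is what survives morphological
    erosion of each class by ``edge_depth_m`` (8-neighbourhood square
    structuring element, one erosion pass per cell of depth); cells at the grid
    or nodata boundary are edge, never core. ``edge_depth_m`` must be a
    non-negative multiple of the cell size.
    """
    h = patches.cell_size
    if edge_depth_m < 0:
        raise ValueError("edge_depth_m must be non-negative")
    depth_cells = edge_depth_m / h
    if abs(depth_cells - round(depth_cells)) > 1e-9:
        raise ValueError(
            f"edge_depth_m ({edge_depth_m}) must be a multiple of the cell size ({h})"
        )
    depth_cells = int(round(depth_cells))
    n = patches.n_patches
    cell_ha = h * h / 10_000.0

    areas = np.bincount(patches.labels.ravel(), minlength=n + 1)[1:]
    area_ha = areas * cell_ha
    perimeter_m = _face_count_per_patch(patches.labels, n) * h

    if depth_cells == 0:
        core_ha = area_ha.copy()
    else:
        core_mask = np.zeros(patches.labels.shape, dtype=bool)
        for code in np.unique(patches.patch_class):
            class_mask = np.isin(
                patches.labels, np.nonzero(patches.patch_class == code)[0] + 1
            )
            eroded = ndimage.binary_erosion(
                class_mask, structure=_STRUCT_8, iterations=depth_cells,
                border_value=0,
            )
            core_mask |= eroded
        core_counts = np.bincount(
            patches.labels[core_mask].ravel(), minlength=n + 1
        )[1:]
        core_ha = core_counts * cell_ha

    return PatchGeometry(
        area_ha=area_ha,
        perimeter_m=perimeter_m,
        core_area_ha=core_ha,
        edge_depth_m=float(edge_depth_m),
        patch_class=patches.patch_class.copy(),
    )
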