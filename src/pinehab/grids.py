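"""Raster grids: ESRI ASCII I/O, grid alignment and point extraction.

The analysis grid follows the ESRI ASCII convention: square cells, the
``(x_origin, y_origin)`` at the lower-left corner, row 0 the northernmost
row.  Cell values are stored as float64 with ``nan`` marking nodata in
memory; the header's ``nodata_value`` is only a serialization token.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "RasterHeader",
    "Raster",
    "RasterParseError",
    "RasterDimensionError",
    "AlignmentError",
    "read_ascii_grid",
    "write_ascii_grid",
    "align_rasters",
    "extract_at_points",
]


class RasterParseError(ValueError):
    """Malformed ESRI ASCII grid header."""


class RasterDimensionError(ValueError):
    """Value block does not match the declared dimensions."""


class AlignmentError(ValueError):
    """Rasters cannot be placed on a common analysis grid."""


@dataclass(frozen=True)
class RasterHeader:
    """Geometry of a square-celled grid (lower-left origin)."""

    n_cols: int
    n_rows: int
    x_origin: float
    y_origin: float
    cell_size: float
    nodata_value: float = -9999.0
    crs_tag: str = ""

    def __post_init__(self) -> None:
        if self.n_cols <= 0 or self.n_rows <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def x_max(self) -> float:
        return self.x_origin + self.n_cols * self.cell_size

    @property
    def y_max(self) -> float:
        return self.y_origin + self.n_rows * self.cell_size

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Map coordinate of the center of cell ``(row, col)``."""
        x = self.x_origin + (col + 0.5) * self.cell_size
        y = self.y_origin + (self.n_rows - row - 0.5) * self.cell_size
        return x, y

    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing map point ``(x, y)``.

        Points exactly on the upper/right edge belong to the last cell.
        """
        col = int(math.floor((x - self.x_origin) / self.cell_size))
        row = self.n_rows - 1 - int(math.floor((y - self.y_origin) / self.cell_size))
        col = min(max(col, 0), self.n_cols - 1) if self.contains(x, y) else col
        row = min(max(row, 0), self.n_rows - 1) if self.contains(x, y) else row
        return row, col

    def contains(self, x: float, y: float) -> bool:
        return (
            self.x_origin <= x <= self.x_max and self.y_origin <= y <= self.y_max
        )

    def geometry_equal(self, other: "RasterHeader", rtol: float = 1e-9) -> bool:
        return (
            self.n_cols == other.n_cols
            and self.n_rows == other.n_rows
            and math.isclose(self.x_origin, other.x_origin, rel_tol=rtol, abs_tol=1e-9)
            and math.isclose(self.y_origin, other.y_origin, rel_tol=rtol, abs_tol=1e-9)
            and math.isclose(self.cell_size, other.cell_size, rel_tol=rtol)
        )


@dataclass
class Raster:
    """A header plus an ``(n_rows, n_cols)`` float array; nan = nodata."""

    header: RasterHeader
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.header.n_rows, self.header.n_cols):
            raise RasterDimensionError(
                f"value array shape {self.values.shape} does not match header "
                f"({self.header.n_rows}, {self.header.n_cols})"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        return np.isfinite(self.values)

    @property
    def finite(self) -> np.ndarray:
        """1-D array of the data cells only."""
        return self.values[self.mask]

    def copy(self) -> "Raster":
        return Raster(self.header, self.values.copy())


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path) -> Raster:
    """Read an ESRI ASCII grid (.asc).

    Header keys ``ncols nrows xllcorner yllcorner cellsize`` are required,
    ``NODATA_value`` is optional (default -9999). Row 1 of the value block
    is the northernmost row.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()

    header: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
            key = parts[0].lower()
            try:
                header[key] = float(parts[1])
            except ValueError as exc:
                raise RasterParseError(f"invalid value for header key '{key}': {parts[1]!r}") from exc
            i += 1
        else:
            break

    for key in _HEADER_KEYS:
        if key not in header:
            raise RasterParseError(f"missing required header key '{key}'")
    for key in ("ncols", "nrows"):
        if header[key] != int(header[key]) or header[key] <= 0:
            raise RasterParseError(f"header key '{key}' must be a positive integer")

    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    nodata = header.get("nodata_value", -9999.0)

    rows: list[np.ndarray] = []
    for j, line in enumerate(lines[i:]):
        if not line.strip():
            continue
        try:
            row = np.array([float(tok) for tok in line.split()])
        except ValueError as exc:
            raise RasterParseError(f"non-numeric value in data row {len(rows) + 1}") from exc
        if row.size != n_cols:
            raise RasterDimensionError(
                f"data row {len(rows) + 1} has {row.size} values, expected {n_cols}"
            )
        rows.append(row)
    if len(rows) != n_rows:
        raise RasterDimensionError(f"found {len(rows)} data rows, expected {n_rows}")

    values = np.vstack(rows)
    values[values == nodata] = np.nan
    hdr = RasterHeader(
        n_cols=n_cols,
        n_rows=n_rows,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"],
        cell_size=header["cellsize"],
        nodata_value=nodata,
    )
    return Raster(hdr, values)


def _fmt(v: float) -> str:
    # repr-style shortest form: exact float round-trip through text
    if v == int(v) and abs(v) < 1e16:
        return str(int(v))
    return repr(float(v))


def write_ascii_grid(raster: Raster, path) -> None:
    """Write an ESRI ASCII grid; nan cells become the header nodata value."""
    h = raster.header
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {h.n_cols}\n")
        fh.write(f"nrows {h.n_rows}\n")
        fh.write(f"xllcorner {_fmt(h.x_origin)}\n")
        fh.write(f"yllcorner {_fmt(h.y_origin)}\n")
        fh.write(f"cellsize {_fmt(h.cell_size)}\n")
        fh.write(f"NODATA_value {_fmt(h.nodata_value)}\n")
        nod = _fmt(h.nodata_value)
        for row in raster.values:
            fh.write(" ".join(nod if not np.isfinite(v) else _fmt(v) for v in row))
            fh.write("\n")


# ---------------------------------------------------------------------------
# Alignment / resampling

def _target_header(rasters: list[Raster], target_cell_size: float | None) -> RasterHeader:
    cell = target_cell_size or max(r.header.cell_size for r in rasters)
    x0 = max(r.header.x_origin for r in rasters)
    y0 = max(r.header.y_origin for r in rasters)
    x1 = min(r.header.x_max for r in rasters)
    y1 = min(r.header.y_max for r in rasters)
    n_cols = int(math.floor((x1 - x0) / cell + 1e-9))
    n_rows = int(math.floor((y1 - y0) / cell + 1e-9))
    if n_cols <= 0 or n_rows <= 0:
        raise AlignmentError("raster extents do not overlap")
    return RasterHeader(
        n_cols=n_cols,
        n_rows=n_rows,
        x_origin=x0,
        y_origin=y0,
        cell_size=cell,
        nodata_value=rasters[0].header.nodata_value,
        crs_tag=rasters[0].header.crs_tag,
    )


def _resample(raster: Raster, target: RasterHeader, categorical: bool) -> Raster:
    src = raster.header
    rows = np.arange(target.n_rows)
    cols = np.arange(target.n_cols)
    # target cell-center map coordinates
    xs = target.x_origin + (cols + 0.5) * target.cell_size
    ys = target.y_origin + (target.n_rows - rows - 0.5) * target.cell_size
    # fractional source array indices of those points
    src_c = (xs - src.x_origin) / src.cell_size - 0.5
    src_r = (src.y_origin + src.n_rows * src.cell_size - ys) / src.cell_size - 0.5
    rr, cc = np.meshgrid(src_r, src_c, indexing="ij")
    coords = np.vstack([rr.ravel(), cc.ravel()])
    if categorical:
        out = ndimage.map_coordinates(
            np.nan_to_num(raster.values, nan=np.nan), coords, order=0, mode="nearest"
        )
    else:
        vals = raster.values
        filled = np.where(np.isfinite(vals), vals, 0.0)
        num = ndimage.map_coordinates(filled, coords, order=1, mode="nearest")
        wt = ndimage.map_coordinates(
            raster.mask.astype(float), coords, order=1, mode="nearest"
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(wt > 0.5, num / np.maximum(wt, 1e-12), np.nan)
    return Raster(target, out.reshape(target.n_rows, target.n_cols))


def align_rasters(
    rasters: list[Raster],
    target_cell_size: float | None = None,
    categorical: list[bool] | None = None,
) -> list[Raster]:
    """Place all rasters on one grid.

    The target cell size defaults to the maximum input cell size (the
    coarsest layer governs, matching the GIS convention of setting the grid
    to the maximum of the input grids); the extent is the spatial
    intersection. Continuous layers are resampled bilinearly, categorical
    layers (land cover) by nearest neighbour.
    """
    if not rasters:
        return []
    if categorical is None:
        categorical = [False] * len(rasters)
    if len(categorical) != len(rasters):
        raise ValueError("categorical flags must match the raster list")
    target = _target_header(rasters, target_cell_size)
    out = []
    for r, cat in zip(rasters, categorical):
        if r.header.geometry_equal(target):
            out.append(r.copy())
        else:
            out.append(_resample(r, target, cat))
    return out


def extract_at_points(raster: Raster, points) -> np.ndarray:
    """Nearest-cell value at each point; nan for out-of-extent or nodata.

    ``points`` is a sequence of objects with ``x``/``y`` attributes (or
    ``(x, y)`` pairs).
    """
    h = raster.header
    out = np.full(len(points), np.nan)
    n_outside = 0
    for i, p in enumerate(points):
        x, y = (p.x, p.y) if hasattr(p, "x") else (p[0], p[1])
        if not h.contains(x, y):
            n_outside += 1
            continue
        row, col = h.cell_index(x, y)
        out[i] = raster.values[row, col]
    if n_outside:
        warnings.warn(f"{n_outside} point(s) fall outside the raster extent", stacklevel=2)
    return out
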