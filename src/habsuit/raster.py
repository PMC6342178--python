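"""Rasters and occurrence points: data model, I/O, and point-to-pixel sampling.

A :class:`Raster` is a single-band 2D grid in the north-up convention: pixel
(row 0, col 0) is the top-left corner, map y decreases as the row index grows,
and pixels are square.  Nodata cells are stored internally as NaN; the original
sentinel (if any) is kept for round-tripping.  Supported on-disk formats are
single-band GeoTIFF (via tifffile, with the standard GeoTIFF georeferencing
tags) and ESRI ASCII grid.  Occurrences are (x, y) map-coordinate points read
from delimited text.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Raster",
    "OccurrenceSet",
    "RasterFormatError",
    "OccurrenceParseError",
    "read_raster",
    "write_raster",
    "read_occurrences",
    "write_occurrences",
    "sample_raster_at_points",
]

# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class RasterFormatError(ValueError):
    """Unsupported or malformed raster file."""


class OccurrenceParseError(ValueError):
    """Malformed occurrence table."""


@dataclass
class Raster:
    """Single-band raster with square pixels, top-left origin.

    Parameters
    ----------
    values : 2D array
        Cell values; NaN marks nodata internally.
    origin_x, origin_y : float
        Map coordinates of the outer corner of pixel (0, 0) (top-left).
    cell_size : float
        Map units per pixel (> 0).
    nodata : float, optional
        Sentinel used on disk; cells equal to it are converted to NaN.
    """

    values: np.ndarray
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 1.0
    nodata: float | None = None

    def __post_init__(self) -> None:
        v = np.array(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 1:
            raise ValueError("raster values must be a non-empty 2D array")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be > 0")
        if self.nodata is not None:
            v[v == self.nodata] = np.nan
        self.values = v

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in map units."""
        return (
            self.origin_x,
            self.origin_y - self.height * self.cell_size,
            self.origin_x + self.width * self.cell_size,
            self.origin_y,
        )

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        return np.isfinite(self.values)

    @property
    def vmin(self) -> float:
        return float(np.nanmin(self.values))

    @property
    def vmax(self) -> float:
        return float(np.nanmax(self.values))

    def finite_values(self) -> np.ndarray:
        return self.values[self.mask]

    def with_values(self, values: np.ndarray) -> "Raster":
        """New raster sharing this raster's georeferencing."""
        return Raster(
            np.asarray(values, dtype=float),
            origin_x=self.origin_x,
            origin_y=self.origin_y,
            cell_size=self.cell_size,
            nodata=self.nodata,
        )

    def aligned_with(self, other: "Raster", rtol: float = 1e-9) -> bool:
        if self.values.shape != other.values.shape:
            return False
        scale = max(abs(self.cell_size), 1.0)
        return (
            math.isclose(self.cell_size, other.cell_size, rel_tol=rtol)
            and abs(self.origin_x - other.origin_x) <= rtol * scale * max(1, self.width)
            and abs(self.origin_y - other.origin_y) <= rtol * scale * max(1, self.height)
        )


@dataclass
class OccurrenceSet:
    """Ordered set of occurrence points in map coordinates."""

    xy: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self) -> None:
        xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        if xy.size and not np.all(np.isfinite(xy)):
            raise ValueError("occurrence coordinates must be finite")
        self.xy = xy

    @property
    def n(self) -> int:
        return self.xy.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.xy[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xy[:, 1]

    def subset(self, idx: np.ndarray) -> "OccurrenceSet":
        return OccurrenceSet(self.xy[idx])


def _write_geotiff(r: Raster, path: Path) -> None:
    data = r.values.astype(np.float32)
    nodata = r.nodata
    if np.isnan(data).any() and nodata is None:
        nodata = -9999.0
    if nodata is not None:
        data = np.where(np.isnan(data), np.float32(nodata), data)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (r.cell_size, r.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, r.origin_x, r.origin_y, 0.0)),
    ]
    if nodata is not None:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, repr(float(nodata))))
    tifffile.imwrite(path, data, photometric="minisblack", extratags=extratags)


def _read_geotiff(path: Path) -> Raster:
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) > 1:
            raise RasterFormatError(
                f"{path}: multi-band GeoTIFF; extract the band of interest "
                "to a single-band file first"
            )
        page = tif.pages[0]
        if getattr(page, "samplesperpixel", 1) > 1:
            raise RasterFormatError(
                f"{path}: multi-sample GeoTIFF; extract a single band first"
            )
        data = page.asarray().astype(float)
        if data.ndim != 2:
            raise RasterFormatError(f"{path}: expected a single-band 2D image")
        cell = 1.0
        ox, oy = 0.0, float(data.shape[0])
        tag = page.tags.get(_TAG_PIXEL_SCALE)
        if tag is not None:
            cell = float(tag.value[0])
        tag = page.tags.get(_TAG_TIEPOINT)
        if tag is not None:
            ox, oy = float(tag.value[3]), float(tag.value[4])
        else:
            oy = data.shape[0] * cell
        nodata = None
        tag = page.tags.get(_TAG_GDAL_NODATA)
        if tag is not None:
            nodata = float(str(tag.value).strip().rstrip("\x00"))
    return Raster(data, origin_x=ox, origin_y=oy, cell_size=cell, nodata=nodata)


def _write_ascii_grid(r: Raster, path: Path) -> None:
    nodata = r.nodata if r.nodata is not None else -9999.0
    vals = np.where(np.isnan(r.values), nodata, r.values)
    yll = r.origin_y - r.height * r.cell_size
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {r.width}\n")
        fh.write(f"nrows {r.height}\n")
        fh.write(f"xllcorner {r.origin_x!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {r.cell_size!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        np.savetxt(fh, vals, fmt="%.10g")


def _read_ascii_grid(path: Path) -> Raster:
    header: dict[str, float] = {}
    data_start = 0
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
            "yllcenter", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            data_start += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise RasterFormatError(f"{path}: missing ASCII grid header field {key}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cell = header["cellsize"]
    if "xllcorner" in header:
        xll = header["xllcorner"]
    elif "xllcenter" in header:
        xll = header["xllcenter"] - cell / 2.0
    else:
        raise RasterFormatError(f"{path}: missing xllcorner/xllcenter")
    if "yllcorner" in header:
        yll = header["yllcorner"]
    elif "yllcenter" in header:
        yll = header["yllcenter"] - cell / 2.0
    else:
        raise RasterFormatError(f"{path}: missing yllcorner/yllcenter")
    values = np.loadtxt(lines[data_start:], dtype=float)
    values = values.reshape(nrows, ncols)
    nodata = header.get("nodata_value")
    return Raster(
        values,
        origin_x=xll,
        origin_y=yll + nrows * cell,
        cell_size=cell,
        nodata=nodata,
    )


def read_raster(path: str | Path) -> Raster:
    """Read a single-band GeoTIFF (.tif/.tiff) or ESRI ASCII grid (.asc)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"raster file not found: {path}")
    ext = path.suffix.lower()
    if ext in (".tif", ".tiff"):
        return _read_geotiff(path)
    if ext == ".asc":
        return _read_ascii_grid(path)
    raise RasterFormatError(f"unsupported raster format: {path}")


def write_raster(r: Raster, path: str | Path) -> None:
    """Write a raster; format chosen by extension (.tif/.tiff or .asc)."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext in (".tif", ".tiff"):
        _write_geotiff(r, path)
    elif ext == ".asc":
        _write_ascii_grid(r, path)
    else:
        raise RasterFormatError(f"unsupported raster format: {path}")


def read_occurrences(
    path: str | Path,
    x_col: str = "x",
    y_col: str = "y",
    delimiter: str | None = None,
) -> OccurrenceSet:
    """Read occurrence points from delimited text (comma default, tab accepted).

    Column names are matched case-insensitively.  Rows are kept in file order.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"occurrence file not found: {path}")
    if delimiter is None:
        df = pd.read_csv(path, sep=None, engine="python")
    else:
        df = pd.read_csv(path, sep=delimiter)
    cols = {str(c).strip().lower(): c for c in df.columns}
    missing = [name for name in (x_col, y_col) if name.lower() not in cols]
    if missing:
        raise OccurrenceParseError(
            f"{path}: missing column(s) {missing}; found {list(df.columns)}"
        )
    out = np.empty((len(df), 2))
    for j, name in enumerate((x_col, y_col)):
        raw = df[cols[name.lower()]]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & raw.notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0]) + 1
            raise OccurrenceParseError(
                f"{path}: non-numeric {name} coordinate at data row {row}"
            )
        if num.isna().any():
            row = int(np.nonzero(num.isna().to_numpy())[0][0]) + 1
            raise OccurrenceParseError(f"{path}: missing {name} at data row {row}")
        out[:, j] = num.to_numpy(dtype=float)
    return OccurrenceSet(out)


def write_occurrences(occ: OccurrenceSet, path: str | Path, x_col: str = "x", y_col: str = "y") -> None:
    pd.DataFrame({x_col: occ.x, y_col: occ.y}).to_csv(path, index=False)


def point_to_pixel(r: Raster, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map coordinates -> (row, col) pixel indices by the floor convention.

    Pixel membership uses half-open intervals [edge, edge + cell_size) in both
    axes, so a point on a shared edge belongs to the pixel with the larger
    index.  Indices may fall outside the grid; callers must range-check.
    """
    col = np.floor((np.asarray(x, float) - r.origin_x) / r.cell_size).astype(np.int64)
    row = np.floor((r.origin_y - np.asarray(y, float)) / r.cell_size).astype(np.int64)
    return row, col


def sample_raster_at_points(r: Raster, occ: OccurrenceSet) -> np.ndarray:
    """Raster value at each point's enclosing pixel; NaN where the point is
    outside the extent or on a nodata pixel.  Order is preserved."""
    out = np.full(occ.n, np.nan)
    if occ.n == 0:
        return out
    row, col = point_to_pixel(r, occ.x, occ.y)
    ok = (row >= 0) & (row < r.height) & (col >= 0) & (col < r.width)
    out[ok] = r.values[row[ok], col[ok]]
    return out
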