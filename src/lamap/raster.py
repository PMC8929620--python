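"""Georeferenced grid rasters: data model, Esri ASCII / GeoTIFF I/O, resampling, cropping.

Conventions used throughout the package:

* square cells, projected metric CRS (coordinates in metres);
* row 0 is the northernmost row, cells stored row-major from the top-left;
* ``(origin_x, origin_y)`` is the *outer corner* of the top-left cell, so the
  centre of cell ``(row, col)`` sits at
  ``origin_x + (col + 0.5) * cell_size`` east and
  ``origin_y - (row + 0.5) * cell_size`` north;
* nodata cells are held as NaN internally and excluded from every statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_NODATA = -9999.0

__all__ = [
    "GridRaster",
    "SitePoint",
    "read_grid",
    "write_grid",
    "resample_moving_average",
    "crop",
    "read_sites",
    "write_sites",
]


class RasterFormatError(ValueError):
    """Malformed raster file (bad header field, non-square cells, ...)."""


class EmptyCropError(ValueError):
    """Crop box does not contain any cell centre."""


@dataclass
class GridRaster:
    """One landscape variable on a rectangular cell grid.

    ``values`` is a float array of shape ``(n_rows, n_cols)`` with NaN marking
    nodata. Units are variable-specific (elevation in metres, slope in
    degrees, ...).
    """

    values: np.ndarray
    origin_x: float
    origin_y: float
    cell_size: float
    crs_label: str = "local-metric"
    variable_name: str = ""
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(min_x, min_y, max_x, max_y) of the outer grid boundary."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y,
        )

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.origin_x + (col + 0.5) * self.cell_size,
            self.origin_y - (row + 0.5) * self.cell_size,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (xs of shape n_cols, ys of shape n_rows) of cell-centre coordinates."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.origin_y - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return xs, ys

    def locate(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing point (x, y); raises if outside the extent."""
        min_x, min_y, max_x, max_y = self.extent
        if not (min_x <= x < max_x and min_y < y <= max_y):
            raise ValueError(f"point ({x}, {y}) outside raster extent {self.extent}")
        col = int((x - self.origin_x) // self.cell_size)
        row = int((self.origin_y - y) // self.cell_size)
        # guard the y == origin_y boundary
        return min(row, self.n_rows - 1), min(col, self.n_cols - 1)

    def contains(self, x: float, y: float) -> bool:
        min_x, min_y, max_x, max_y = self.extent
        return min_x <= x < max_x and min_y < y <= max_y

    def like(self, values: np.ndarray, variable_name: str | None = None) -> "GridRaster":
        """New raster with the same geometry but different values."""
        if values.shape != self.values.shape:
            raise ValueError("shape mismatch")
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            variable_name=self.variable_name if variable_name is None else variable_name,
        )


@dataclass
class SitePoint:
    """One known-site record: planar coordinates plus period / split-role labels."""

    site_id: str
    x: float
    y: float
    period: str = "unknown"  # pre10k | post10k | unknown
    role: str = "unassigned"  # train | validate | unassigned

    def __post_init__(self) -> None:
        if self.period not in {"pre10k", "post10k", "unknown"}:
            raise ValueError(f"unknown period label {self.period!r}")
        if self.role not in {"train", "validate", "unassigned"}:
            raise ValueError(f"unknown role {self.role!r}")


# ---------------------------------------------------------------------------
# Esri ASCII grid dialect

_ASCII_HEADER_KEYS = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}


def _read_esri_ascii(path: Path) -> GridRaster:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in _ASCII_HEADER_KEYS:
                try:
                    header[parts[0].lower()] = float(parts[1])
                except ValueError as exc:
                    raise RasterFormatError(
                        f"bad value for header field {parts[0]!r}: {parts[1]!r}"
                    ) from exc
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh, dtype=float, ndmin=2)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise RasterFormatError(f"missing header field {key!r}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if data.shape != (nrows, ncols):
        raise RasterFormatError(
            f"data block is {data.shape}, header says ({nrows}, {ncols})"
        )
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    values = np.where(data == nodata, np.nan, data)
    return GridRaster(
        values=values,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + nrows * header["cellsize"],
        cell_size=header["cellsize"],
        nodata=nodata,
        variable_name=Path(path).stem,
    )


def _write_esri_ascii(raster: GridRaster, path: Path) -> None:
    nrows, ncols = raster.values.shape
    yll = raster.origin_y - nrows * raster.cell_size
    out = np.where(np.isnan(raster.values), raster.nodata, raster.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {raster.origin_x:.6f}\n")
        fh.write(f"yllcorner {yll:.6f}\n")
        fh.write(f"cellsize {raster.cell_size:.6f}\n")
        fh.write(f"NODATA_value {raster.nodata:.6g}\n")
        for row in out:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# GeoTIFF dialect (single band, via tifffile with standard GeoTIFF tags)

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def _read_geotiff(path: Path) -> GridRaster:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray().astype(float)
        if data.ndim != 2:
            raise RasterFormatError("only single-band GeoTIFFs are supported")
        tags = {tag.code: tag.value for tag in page.tags.values()}
    scale = tags.get(_TAG_MODEL_PIXEL_SCALE)
    tiepoint = tags.get(_TAG_MODEL_TIEPOINT)
    if scale is None or tiepoint is None:
        raise RasterFormatError("missing GeoTIFF georeferencing tags")
    sx, sy = float(scale[0]), float(scale[1])
    if abs(sx - sy) > 1e-9 * max(sx, sy):
        raise RasterFormatError(f"non-square cells unsupported: {sx} x {sy}")
    # tiepoint maps raster (i, j) = (0, 0) to (x, y) of the top-left corner
    origin_x = float(tiepoint[3]) - float(tiepoint[0]) * sx
    origin_y = float(tiepoint[4]) + float(tiepoint[1]) * sy
    nodata = DEFAULT_NODATA
    if _TAG_GDAL_NODATA in tags:
        try:
            nodata = float(str(tags[_TAG_GDAL_NODATA]).strip("\x00"))
        except ValueError as exc:
            raise RasterFormatError("bad GDAL nodata tag") from exc
    values = np.where(data == nodata, np.nan, data)
    return GridRaster(
        values=values,
        origin_x=origin_x,
        origin_y=origin_y,
        cell_size=sx,
        nodata=nodata,
        variable_name=Path(path).stem,
    )


def _write_geotiff(raster: GridRaster, path: Path) -> None:
    import tifffile

    out = np.where(np.isnan(raster.values), raster.nodata, raster.values)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (raster.cell_size, raster.cell_size, 0.0)),
        (
            _TAG_MODEL_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, raster.origin_x, raster.origin_y, 0.0),
        ),
        (_TAG_GDAL_NODATA, "s", 0, f"{raster.nodata:.6g}"),
    ]
    tifffile.imwrite(path, out.astype(np.float64), extratags=extratags)


_DIALECTS = {"esri_ascii", "geotiff"}


def _infer_dialect(path: Path) -> str:
    return "geotiff" if Path(path).suffix.lower() in {".tif", ".tiff"} else "esri_ascii"


def read_grid(path: str | Path, dialect: str | None = None) -> GridRaster:
    """Read a single-band raster in either supported dialect.

    With ``dialect=None`` the dialect is inferred from the file suffix
    (``.tif``/``.tiff`` means GeoTIFF, anything else Esri ASCII).
    """
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    if dialect == "esri_ascii":
        return _read_esri_ascii(path)
    return _read_geotiff(path)


def write_grid(raster: GridRaster, path: str | Path, dialect: str | None = None) -> None:
    """Write a raster; the file round-trips through :func:`read_grid`."""
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    if dialect == "esri_ascii":
        _write_esri_ascii(raster, path)
    else:
        _write_geotiff(raster, path)


# ---------------------------------------------------------------------------
# Preprocessing

def resample_moving_average(raster: GridRaster, factor: int) -> GridRaster:
    """Aggregate to ``factor`` x coarser cells by block-aligned averaging.

    Each output cell is the mean of the valid cells in its ``factor x factor``
    input block; all-nodata blocks stay nodata. Trailing rows/columns that do
    not fill a complete block are dropped.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return replace(raster, values=raster.values.copy())
    nrows = (raster.n_rows // factor) * factor
    ncols = (raster.n_cols // factor) * factor
    if nrows == 0 or ncols == 0:
        raise ValueError("grid smaller than one aggregation block")
    block = raster.values[:nrows, :ncols].reshape(
        nrows // factor, factor, ncols // factor, factor
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-nodata blocks
        out = np.nanmean(block, axis=(1, 3))
    return replace(raster, values=out, cell_size=raster.cell_size * factor)


def crop(
    raster: GridRaster, min_x: float, min_y: float, max_x: float, max_y: float
) -> GridRaster:
    """Sub-grid of cells whose centres fall in the half-open box [min_x, max_x) x [min_y, max_y)."""
    xs, ys = raster.cell_centers()
    cols = np.where((xs >= min_x) & (xs < max_x))[0]
    rows = np.where((ys >= min_y) & (ys < max_y))[0]
    if cols.size == 0 or rows.size == 0:
        raise EmptyCropError("crop box contains no cell centres")
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    return replace(
        raster,
        values=raster.values[r0:r1, c0:c1].copy(),
        origin_x=raster.origin_x + c0 * raster.cell_size,
        origin_y=raster.origin_y - r0 * raster.cell_size,
    )


# ---------------------------------------------------------------------------
# Site tables

def read_sites(path: str | Path) -> list[SitePoint]:
    """Read a sites CSV (columns site_id,x,y,period,role; header required)."""
    df = pd.read_csv(path, dtype={"site_id": str})
    required = {"site_id", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sites CSV missing columns: {sorted(missing)}")
    if "period" not in df.columns:
        df["period"] = "unknown"
    if "role" not in df.columns:
        df["role"] = "unassigned"
    df["period"] = df["period"].fillna("unknown")
    df["role"] = df["role"].fillna("unassigned")
    return [
        SitePoint(str(r.site_id), float(r.x), float(r.y), str(r.period), str(r.role))
        for r in df.itertuples()
    ]


def write_sites(sites: list[SitePoint], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"site_id": s.site_id, "x": s.x, "y": s.y, "period": s.period, "role": s.role}
            for s in sites
        ]
    ).to_csv(path, index=False)
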