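"""Raster data model and I/O shared by every stage of the pipeline.

A :class:`Grid` is a single-band, north-up raster in a projected coordinate
system (meters).  Values are stored row-major with row 0 the northernmost row;
the georeference is the *outer* corner of the top-left cell, and cell values
represent cell centers.  ESRI ASCII grids (which carry the lower-left corner)
are converted to this convention on read and back on write.

Missing cells are represented as NaN in memory and as the nodata sentinel on
disk.  No reprojection is performed: the CRS is carried as an opaque label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Grid",
    "GridFormatError",
    "read_grid",
    "write_grid",
    "pixel_id",
    "pixel_ids",
    "extract_at",
    "read_samples",
    "write_samples",
]


class GridFormatError(ValueError):
    """Raised when a raster file does not parse under the named standard."""


@dataclass
class Grid:
    """Single-band georeferenced raster.

    Attributes
    ----------
    values : ndarray, shape (n_rows, n_cols)
        Cell values; NaN marks nodata. Row 0 is the northernmost row.
    x_origin, y_origin : float
        Outer corner of the top-left cell, in projected meters.
    cell_size : float
        Square cell edge length in meters (> 0).
    nodata : float
        Sentinel written to disk for missing cells.
    crs_label : str
        Opaque description of the projected frame.
    """

    values: np.ndarray
    x_origin: float
    y_origin: float
    cell_size: float
    nodata: float = -9999.0
    crs_label: str = "projected-meters"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max) outer bounds."""
        return (
            self.x_origin,
            self.y_origin - self.n_rows * self.cell_size,
            self.x_origin + self.n_cols * self.cell_size,
            self.y_origin,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate vectors of column / row centers."""
        x = self.x_origin + (np.arange(self.n_cols) + 0.5) * self.cell_size
        y = self.y_origin - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return x, y

    def like(self, values: np.ndarray, **overrides) -> "Grid":
        """New grid sharing this georeference with different values."""
        g = replace(self, values=np.asarray(values, dtype=float))
        for k, v in overrides.items():
            setattr(g, k, v)
        return g


# ---------------------------------------------------------------------------
# File I/O

_ASC_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def _read_esri_ascii(path: str) -> Grid:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _ASC_HEADER_KEYS + ("nodata_value",):
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError as exc:
                raise GridFormatError(f"{path}: bad header line {i + 1}: {line!r}") from exc
        else:
            break
    for key in _ASC_HEADER_KEYS:
        if key not in header:
            raise GridFormatError(f"{path}: missing header field {key!r}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    nodata = header.get("nodata_value", -9999.0)
    rows = []
    for j, line in enumerate(lines[i:], start=i + 1):
        if not line.strip():
            continue
        try:
            row = np.array(line.split(), dtype=float)
        except ValueError as exc:
            raise GridFormatError(f"{path}: non-numeric value on line {j}") from exc
        if row.size != ncols:
            raise GridFormatError(
                f"{path}: line {j} has {row.size} values, expected ncols={ncols}"
            )
        rows.append(row)
    if len(rows) != nrows:
        raise GridFormatError(f"{path}: found {len(rows)} data rows, expected nrows={nrows}")
    values = np.vstack(rows)
    values[values == nodata] = np.nan
    cell = header["cellsize"]
    return Grid(
        values=values,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + nrows * cell,
        cell_size=cell,
        nodata=nodata,
    )


def _write_esri_ascii(g: Grid, path: str) -> None:
    vals = np.where(np.isnan(g.values), g.nodata, g.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {g.n_cols}\n")
        fh.write(f"nrows {g.n_rows}\n")
        fh.write(f"xllcorner {g.x_origin:.10g}\n")
        fh.write(f"yllcorner {g.y_origin - g.n_rows * g.cell_size:.10g}\n")
        fh.write(f"cellsize {g.cell_size:.10g}\n")
        fh.write(f"NODATA_value {g.nodata:.10g}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


# GeoTIFF tag numbers: pixel scale, tiepoint, GDAL nodata.
_TAG_SCALE, _TAG_TIEPOINT, _TAG_NODATA = 33550, 33922, 42113


def _read_geotiff(path: str) -> Grid:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        if values.ndim != 2:
            raise GridFormatError(f"{path}: expected a single-band raster")
        tags = page.tags
        if _TAG_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise GridFormatError(f"{path}: missing GeoTIFF georeference tags")
        sx, sy = tags[_TAG_SCALE].value[:2]
        tie = tags[_TAG_TIEPOINT].value
        # tiepoint maps raster (i, j, k) -> model (x, y, z); we require (0, 0).
        x0, y0 = tie[3] - tie[0] * sx, tie[4] + tie[1] * sy
        if abs(sx - sy) > 1e-9 * max(sx, sy):
            raise GridFormatError(f"{path}: non-square cells ({sx} x {sy}) unsupported")
        nodata = -9999.0
        if _TAG_NODATA in tags:
            nodata = float(tags[_TAG_NODATA].value)
        crs = "projected-meters"
        desc = tags.get(270)
        if desc is not None:
            try:
                crs = json.loads(desc.value).get("crs_label", crs)
            except (ValueError, AttributeError):
                pass
        values[values == nodata] = np.nan
        return Grid(values, x_origin=x0, y_origin=y0, cell_size=sx, nodata=nodata, crs_label=crs)


def _write_geotiff(g: Grid, path: str) -> None:
    import tifffile

    vals = np.where(np.isnan(g.values), g.nodata, g.values)
    extratags = [
        (_TAG_SCALE, "d", 3, (g.cell_size, g.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.x_origin, g.y_origin, 0.0)),
        (_TAG_NODATA, "s", 0, f"{g.nodata:.10g}"),
    ]
    tifffile.imwrite(
        path,
        vals,
        extratags=extratags,
        description=json.dumps({"crs_label": g.crs_label}),
    )


def read_grid(path: str, format: str | None = None) -> Grid:
    """Read a raster; ``format`` is ``esri_ascii`` or ``geotiff`` (inferred
    from the extension when omitted)."""
    if format is None:
        format = "geotiff" if str(path).lower().endswith((".tif", ".tiff")) else "esri_ascii"
    if format == "esri_ascii":
        return _read_esri_ascii(str(path))
    if format == "geotiff":
        return _read_geotiff(str(path))
    raise ValueError(f"unknown raster format {format!r}")


def write_grid(g: Grid, path: str, format: str | None = None) -> None:
    if format is None:
        format = "geotiff" if str(path).lower().endswith((".tif", ".tiff")) else "esri_ascii"
    if format == "esri_ascii":
        _write_esri_ascii(g, str(path))
    elif format == "geotiff":
        _write_geotiff(g, str(path))
    else:
        raise ValueError(f"unknown raster format {format!r}")


# ---------------------------------------------------------------------------
# Coordinate <-> pixel mapping

def pixel_ids(g: Grid, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized half-open pixel membership.

    Cells are half-open (a point on a shared edge belongs to the cell with the
    larger row/col index) except on the grid's outer maximum edge, which maps
    inward, so every in-bounds point has exactly one pixel.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xmin, ymin, xmax, ymax = g.bounds
    if np.any((x < xmin) | (x > xmax) | (y < ymin) | (y > ymax)):
        bad = np.flatnonzero((x < xmin) | (x > xmax) | (y < ymin) | (y > ymax))
        raise ValueError(f"point(s) outside grid bounds at index {bad[:5].tolist()}")
    col = np.floor((x - g.x_origin) / g.cell_size).astype(np.int64)
    row = np.floor((g.y_origin - y) / g.cell_size).astype(np.int64)
    col = np.minimum(col, g.n_cols - 1)
    row = np.minimum(row, g.n_rows - 1)
    return row, col


def pixel_id(g: Grid, x: float, y: float) -> tuple[int, int]:
    """(row, col) of the cell containing the point ``(x, y)``."""
    r, c = pixel_ids(g, np.array([x]), np.array([y]))
    return int(r[0]), int(c[0])


def extract_at(g: Grid, samples: pd.DataFrame) -> np.ndarray:
    """Value of the containing cell for each sample (no interpolation).

    Samples landing on nodata cells return NaN (flagged missing, never
    dropped).  ``samples`` needs columns ``x`` and ``y``.
    """
    r, c = pixel_ids(g, samples["x"].to_numpy(), samples["y"].to_numpy())
    return g.values[r, c]


# ---------------------------------------------------------------------------
# Sample table

_SAMPLE_COLS = ["id", "x", "y", "alt", "plot_id"]


def read_samples(path: str) -> pd.DataFrame:
    """Read the sample table CSV (columns ``id,x,y,alt,plot_id``)."""
    df = pd.read_csv(path, dtype={"id": str, "plot_id": str})
    missing = [c for c in _SAMPLE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: sample table missing columns {missing}")
    if df["id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    if not np.isfinite(df[["x", "y"]].to_numpy()).all():
        raise ValueError(f"{path}: non-finite coordinates")
    if df["plot_id"].isna().any():
        raise ValueError(f"{path}: missing plot_id")
    return df[_SAMPLE_COLS]


def write_samples(df: pd.DataFrame, path: str) -> None:
    df[_SAMPLE_COLS].to_csv(path, index=False, float_format="%.10g")
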