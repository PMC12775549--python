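"""Forest cover in circular buffers around traps, from a land-cover raster.

The raster is a single-band integer class grid in a projected planar frame
(meters).  Cover is the share of forest-class pixels among valid (non-nodata)
pixels whose *centers* fall within the buffer radius — the pixel-center rule
pins the circle-to-grid discretization exactly, so results are reproducible
against a per-pixel enumeration.

Rasters are read/written as ESRI ASCII grids (plain text); a single-band TIFF
can be read when tifffile is available.  Geographic (lon/lat-looking)
coordinates are refused unless forced, since buffer radii are in meters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ClassRaster",
    "forest_cover",
    "batch_cover",
    "read_ascii_grid",
    "write_ascii_grid",
    "MAPBIOMAS_FOREST",
    "SYNTHETIC_FOREST",
]

# MapBiomas collection codes for native forested vegetation: forest formation,
# savanna formation, mangrove, floodable forest, wooded sandbank vegetation.
MAPBIOMAS_FOREST = frozenset({3, 4, 5, 6, 49})
# Synthetic rasters use 1 = forest, 0 = non-forest.
SYNTHETIC_FOREST = frozenset({1})


@dataclass
class ClassRaster:
    """Single-band integer class raster on a regular grid.

    ``grid[0, 0]`` is the upper-left pixel; ``origin`` is the (x, y) of the
    grid's upper-left *corner* in projected meters; y decreases down rows.
    """

    grid: np.ndarray
    origin: tuple[float, float]
    pixel_size: float = 30.0
    nodata: int = -9999

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("raster grid must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def n_rows(self) -> int:
        return self.grid.shape[0]

    @property
    def n_cols(self) -> int:
        return self.grid.shape[1]

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every pixel center (2-D arrays)."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.n_cols) + 0.5) * self.pixel_size
        ys = y0 - (np.arange(self.n_rows) + 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)

    def pixel_at(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the pixel containing the point; raises if outside."""
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.pixel_size))
        row = int(np.floor((y0 - y) / self.pixel_size))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({x}, {y}) outside the raster")
        return row, col


def forest_cover(
    raster: ClassRaster,
    point: tuple[float, float],
    radius: float = 100.0,
    forest_set: frozenset[int] | set[int] = SYNTHETIC_FOREST,
) -> tuple[float, int, int]:
    """Proportion of forest pixels within a circular buffer around a point.

    Pixels are included when their centers lie within ``radius`` of the
    point; nodata pixels are excluded from the denominator.  ``radius = 0``
    degenerates to the point's own pixel.  Returns
    ``(proportion, n_valid_pixels, n_nodata_pixels)``.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    x, y = point
    if radius == 0:
        row, col = raster.pixel_at(x, y)
        code = raster.grid[row, col]
        if code == raster.nodata:
            raise ValueError("trap pixel is nodata")
        return (1.0 if int(code) in forest_set else 0.0), 1, 0
    # restrict to the bounding window of the buffer for speed
    x0, y0 = raster.origin
    px = raster.pixel_size
    col_lo = max(0, int(np.floor((x - radius - x0) / px)))
    col_hi = min(raster.n_cols, int(np.ceil((x + radius - x0) / px)))
    row_lo = max(0, int(np.floor((y0 - (y + radius)) / px)))
    row_hi = min(raster.n_rows, int(np.ceil((y0 - (y - radius)) / px)))
    if col_lo >= col_hi or row_lo >= row_hi:
        raise ValueError("buffer does not intersect the raster")
    sub = raster.grid[row_lo:row_hi, col_lo:col_hi]
    cx = x0 + (np.arange(col_lo, col_hi) + 0.5) * px
    cy = y0 - (np.arange(row_lo, row_hi) + 0.5) * px
    gx, gy = np.meshgrid(cx, cy)
    inside = (gx - x) ** 2 + (gy - y) ** 2 <= radius**2
    if not inside.any():
        raise ValueError("no pixel center falls within the buffer")
    codes = sub[inside]
    valid = codes != raster.nodata
    n_nodata = int((~valid).sum())
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("all pixels within the buffer are nodata")
    forest = np.isin(codes[valid], list(forest_set))
    return float(forest.mean()), n_valid, n_nodata


def batch_cover(
    raster: ClassRaster,
    traps: pd.DataFrame,
    radius: float = 100.0,
    forest_set: frozenset[int] | set[int] = SYNTHETIC_FOREST,
    force_geographic: bool = False,
) -> pd.DataFrame:
    """Forest cover for every trap in a trap table (columns trap_id, x, y).

    Traps whose buffer misses the raster are flagged (``ok = False``), never
    silently dropped.  Coordinates that look geographic (|x| <= 180 and
    |y| <= 90 for every trap) are refused unless ``force_geographic``.
    """
    xs, ys = traps["x"].to_numpy(float), traps["y"].to_numpy(float)
    if len(xs) and not force_geographic:
        if (np.abs(xs) <= 180).all() and (np.abs(ys) <= 90).all():
            raise ValueError(
                "trap coordinates look geographic (lon/lat); buffers need "
                "projected meters — reproject, or pass force_geographic=True"
            )
    rows = []
    for trap_id, x, y in zip(traps["trap_id"], xs, ys):
        try:
            prop, n_valid, n_nodata = forest_cover(raster, (x, y), radius, forest_set)
            rows.append((trap_id, prop, n_valid, n_nodata, True, ""))
        except ValueError as exc:
            rows.append((trap_id, np.nan, 0, 0, False, str(exc)))
    return pd.DataFrame(
        rows,
        columns=["trap_id", "forest_cover", "n_pixels", "n_nodata", "ok", "note"],
    )


def write_ascii_grid(raster: ClassRaster, path: str | Path) -> None:
    """Write an ESRI ASCII grid (plain-text raster interchange format)."""
    x0, y0 = raster.origin
    yll = y0 - raster.n_rows * raster.pixel_size
    header = (
        f"ncols {raster.n_cols}\n"
        f"nrows {raster.n_rows}\n"
        f"xllcorner {x0}\n"
        f"yllcorner {yll}\n"
        f"cellsize {raster.pixel_size}\n"
        f"NODATA_value {raster.nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.grid, fmt="%d")


def read_ascii_grid(path: str | Path) -> ClassRaster:
    """Read an ESRI ASCII grid."""
    meta: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            meta[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    grid = np.loadtxt(lines[n_header:], dtype=int)
    grid = np.atleast_2d(grid)
    nrows, ncols = int(meta["nrows"]), int(meta["ncols"])
    if grid.shape != (nrows, ncols):
        grid = grid.reshape(nrows, ncols)
    y0 = meta["yllcorner"] + nrows * meta["cellsize"]
    return ClassRaster(
        grid=grid,
        origin=(meta["xllcorner"], y0),
        pixel_size=meta["cellsize"],
        nodata=int(meta.get("nodata_value", -9999)),
    )


def read_tiff(path: str | Path, origin: tuple[float, float], pixel_size: float = 30.0,
              nodata: int = -9999) -> ClassRaster:
    """Read a single-band integer TIFF (georeferencing supplied by caller)."""
    try:
        import tifffile
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading TIFF rasters requires tifffile") from exc
    grid = np.asarray(tifffile.imread(str(path)))
    if grid.ndim != 2:
        raise ValueError("expected a single-band raster")
    return ClassRaster(grid=grid.astype(int), origin=origin, pixel_size=pixel_size, nodata=nodata)
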