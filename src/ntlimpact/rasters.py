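"""Core raster containers: the analysis grid and dated radiance stacks.

All radiance values are in nW/cm²/sr on a shared equal-area grid.  Missing
data is represented by NaN throughout; every operation propagates it.
"""
from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["Grid", "RasterStack", "read_raster", "write_raster",
           "read_stack", "write_stack"]


@dataclass(frozen=True)
class Grid:
    """Shared raster geometry: an equal-area grid of square pixels.

    Parameters
    ----------
    rows, cols : int
        Grid shape.
    pixel_size : float
        Side of a pixel in metres (default 500 m).
    equal_area : bool
        Whether the grid is an equal-area projection.  Area statistics
        refuse to run on non-equal-area grids.
    """

    rows: int
    cols: int
    pixel_size: float = 500.0
    equal_area: bool = True

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("grid must have positive shape")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    @property
    def pixel_area_km2(self) -> float:
        """Area of one pixel in km² (pixel_size²)."""
        return self.pixel_size ** 2 / 1e6

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-center coordinates in metres: (x per column, y per row).

        x increases with column index; y increases upward, so row 0 is the
        top of the grid.
        """
        x = (np.arange(self.cols) + 0.5) * self.pixel_size
        y = (self.rows - np.arange(self.rows) - 0.5) * self.pixel_size
        return x, y

    def check_compatible(self, other: "Grid") -> None:
        if self != other:
            raise ValueError(f"grid mismatch: {self} vs {other}")


def _as_dates(dates) -> tuple[dt.date, ...]:
    out = []
    for d in dates:
        if isinstance(d, str):
            d = dt.date.fromisoformat(d)
        elif isinstance(d, dt.datetime):
            d = d.date()
        out.append(d)
    return tuple(out)


@dataclass
class RasterStack:
    """An ordered set of dated radiance layers on one shared grid.

    ``data`` has shape ``(n_dates, rows, cols)``; ``moonlit`` flags dates
    whose scenes are contaminated by lunar illumination.
    """

    dates: tuple[dt.date, ...]
    data: np.ndarray
    grid: Grid
    moonlit: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dates = _as_dates(self.dates)
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("stack data must be 3-D (dates, rows, cols)")
        if self.data.shape != (len(self.dates), *self.grid.shape):
            raise ValueError(
                f"data shape {self.data.shape} does not match "
                f"{len(self.dates)} dates on grid {self.grid.shape}")
        if any(b <= a for a, b in zip(self.dates, self.dates[1:])):
            raise ValueError("dates must be strictly increasing")
        if self.moonlit is None:
            self.moonlit = np.zeros(len(self.dates), dtype=bool)
        self.moonlit = np.asarray(self.moonlit, dtype=bool)
        if self.moonlit.shape != (len(self.dates),):
            raise ValueError("moonlit flags must be one per date")

    def __len__(self) -> int:
        return len(self.dates)

    def copy(self) -> "RasterStack":
        return RasterStack(self.dates, self.data.copy(), self.grid,
                           self.moonlit.copy())

    def layer(self, date: dt.date) -> np.ndarray:
        return self.data[self.dates.index(date)]

    def select(self, keep: np.ndarray) -> "RasterStack":
        """Subset by a boolean mask over dates (order preserved)."""
        keep = np.asarray(keep, dtype=bool)
        dates = tuple(d for d, k in zip(self.dates, keep) if k)
        return RasterStack(dates, self.data[keep], self.grid,
                           self.moonlit[keep])

    def select_period(self, start: dt.date, end: dt.date) -> "RasterStack":
        """Subset to dates in the closed interval [start, end]."""
        keep = np.array([start <= d <= end for d in self.dates])
        return self.select(keep)

    def mean_layer(self) -> np.ndarray:
        """Per-pixel mean over dates, ignoring NaN days."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.data, axis=0)


# ---------------------------------------------------------------------------
# TIFF I/O.  Grid geometry and per-layer metadata travel in the TIFF
# description tag as JSON, keeping each raster a single self-describing file.
# ---------------------------------------------------------------------------

def _grid_meta(grid: Grid) -> dict:
    return {"rows": grid.rows, "cols": grid.cols,
            "pixel_size": grid.pixel_size, "equal_area": grid.equal_area}


def _grid_from_meta(meta: dict) -> Grid:
    return Grid(rows=int(meta["rows"]), cols=int(meta["cols"]),
                pixel_size=float(meta["pixel_size"]),
                equal_area=bool(meta["equal_area"]))


def write_raster(path, array: np.ndarray, grid: Grid, **extra) -> None:
    import tifffile

    meta = {"grid": _grid_meta(grid), **extra}
    tifffile.imwrite(str(path), np.asarray(array),
                     description=json.dumps(meta))


def read_raster(path) -> tuple[np.ndarray, Grid, dict]:
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray()
        meta = json.loads(tif.pages[0].description)
    grid = _grid_from_meta(meta.pop("grid"))
    return arr, grid, meta


def write_stack(directory, stack: RasterStack, prefix: str = "ntl") -> None:
    """Write one float32 TIFF per date (``<prefix>_<ISO date>.tif``)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, d in enumerate(stack.dates):
        write_raster(directory / f"{prefix}_{d.isoformat()}.tif",
                     stack.data[i].astype(np.float32), stack.grid,
                     date=d.isoformat(), moonlit=bool(stack.moonlit[i]))


def read_stack(directory, prefix: str = "ntl") -> RasterStack:
    directory = Path(directory)
    paths = sorted(directory.glob(f"{prefix}_*.tif"))
    if not paths:
        raise FileNotFoundError(f"no '{prefix}_*.tif' rasters in {directory}")
    layers, dates, moonlit, grid = [], [], [], None
    for p in paths:
        arr, g, meta = read_raster(p)
        grid = grid or g
        grid.check_compatible(g)
        layers.append(np.asarray(arr, dtype=np.float64))
        dates.append(dt.date.fromisoformat(meta["date"]))
        moonlit.append(bool(meta.get("moonlit", False)))
    order = np.argsort(dates)
    return RasterStack(tuple(dates[i] for i in order),
                       np.stack([layers[i] for i in order]),
                       grid, np.array(moonlit)[order])
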