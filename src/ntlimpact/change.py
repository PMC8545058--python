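"""Development-corrected radiance change detection.

The per-pixel change statistic is

    CNTL_i = R_i − r_i − D_i,      D_i = d_i − d′_i,

where R_i is the mean retained daily radiance over the outbreak period,
r_i the lunar-matched previous-year baseline, and the development index D_i
the pre-outbreak year-over-year increment (two configurable aggregation
windows) that removes secular growth from the signal.  Pixels are classed
decrease / background / increase by strict thresholds (default −1 and 3
nW/cm²/sr): CNTL < low ⇒ decrease, CNTL > high ⇒ increase, else background.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rasters import Grid, RasterStack
from .zonemap import ZoneMap

__all__ = ["CLASS_BACKGROUND", "CLASS_DECREASE", "CLASS_INCREASE",
           "ChangeRaster", "existing_infections", "add_existing_infections",
           "development_index", "cntl", "affected_area"]

CLASS_BACKGROUND, CLASS_DECREASE, CLASS_INCREASE = 0, 1, 2

DEFAULT_THRESHOLDS = (-1.0, 3.0)


def existing_infections(confirmed, cured, dead):
    """Existing infections ECon = confirmed − cured − dead (elementwise).

    Raises ``ValueError`` when cured + dead exceeds confirmed anywhere —
    such rows are data errors and must be quarantined by the caller (see
    :func:`add_existing_infections`).
    """
    con = np.asarray(confirmed)
    c = np.asarray(cured)
    d = np.asarray(dead)
    if (con < 0).any() or (c < 0).any() or (d < 0).any():
        raise ValueError("case counts must be nonnegative")
    econ = con - c - d
    if (econ < 0).any():
        raise ValueError("cured + dead exceeds confirmed")
    return econ if econ.ndim else econ.item()


def add_existing_infections(table: pd.DataFrame
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Append an ``existing`` column; invalid rows are quarantined.

    Returns (valid table with ``existing``, quarantined rows).
    """
    t = table.copy()
    bad = (t["confirmed"] < t["cured"] + t["dead"]) \
        | (t[["confirmed", "cured", "dead"]] < 0).any(axis=1)
    quarantined = t[bad].copy()
    t = t[~bad].copy()
    t["existing"] = t["confirmed"] - t["cured"] - t["dead"]
    return t, quarantined


def development_index(recent: np.ndarray, prior: np.ndarray,
                      grid: Grid | None = None,
                      prior_grid: Grid | None = None) -> np.ndarray:
    """D = recent − prior, elementwise; NaN propagates.

    ``recent``/``prior`` are pre-outbreak aggregate composites for the
    analysis-side and previous-side windows (e.g. Dec 2019 vs Dec 2018).
    """
    if grid is not None and prior_grid is not None:
        grid.check_compatible(prior_grid)
    recent = np.asarray(recent, dtype=np.float64)
    prior = np.asarray(prior, dtype=np.float64)
    if recent.shape != prior.shape:
        raise ValueError("development composites have mismatched shapes")
    return recent - prior


@dataclass
class ChangeRaster:
    """Per-pixel CNTL with decrease/background/increase classes."""

    cntl: np.ndarray
    classes: np.ndarray          # uint8 codes, CLASS_* above
    thresholds: tuple[float, float]
    grid: Grid

    @property
    def decrease_mask(self) -> np.ndarray:
        return self.classes == CLASS_DECREASE

    @property
    def increase_mask(self) -> np.ndarray:
        return self.classes == CLASS_INCREASE

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.cntl)


def cntl(outbreak_mean: np.ndarray, baseline: np.ndarray,
         development: np.ndarray | float, grid: Grid,
         thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
         ) -> ChangeRaster:
    """Compute CNTL = R − r − D and classify pixels by strict thresholds.

    ``outbreak_mean`` is the per-pixel mean of the retained outbreak-period
    daily layers; ``baseline`` the matched previous-year composite.  Values
    exactly at a threshold are background.  NaN in any operand yields NaN
    CNTL and no class.
    """
    low, high = thresholds
    if low >= high:
        raise ValueError("thresholds must satisfy low < high")
    r_mean = np.asarray(outbreak_mean, dtype=np.float64)
    base = np.asarray(baseline, dtype=np.float64)
    dev = np.broadcast_to(np.asarray(development, dtype=np.float64),
                          r_mean.shape)
    if r_mean.shape != grid.shape or base.shape != grid.shape:
        raise ValueError("operand shape does not match grid")
    c = r_mean - base - dev
    classes = np.full(c.shape, CLASS_BACKGROUND, dtype=np.uint8)
    with np.errstate(invalid="ignore"):
        classes[c < low] = CLASS_DECREASE
        classes[c > high] = CLASS_INCREASE
    classes[~np.isfinite(c)] = CLASS_BACKGROUND
    return ChangeRaster(c, classes, (low, high), grid)


def outbreak_mean(stack: RasterStack) -> np.ndarray:
    """Per-pixel mean of the stack's layers (the R_i aggregate)."""
    return stack.mean_layer()


def affected_area(change: ChangeRaster, zones: ZoneMap) -> pd.DataFrame:
    """Per-zone affected areas in km² on the equal-area grid.

    area_total = area_decrease + area_increase; background and nodata
    pixels contribute nothing.
    """
    if not change.grid.equal_area:
        raise ValueError("affected areas require an equal-area grid")
    change.grid.check_compatible(zones.grid)
    px = change.grid.pixel_area_km2
    rows = []
    for z in zones.zone_ids:
        m = zones.mask(z)
        dec = int((change.decrease_mask & m).sum())
        inc = int((change.increase_mask & m).sum())
        rows.append((z, dec * px, inc * px, (dec + inc) * px))
    return pd.DataFrame(rows, columns=["zone_id", "area_decrease_km2",
                                       "area_increase_km2", "area_total_km2"])
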