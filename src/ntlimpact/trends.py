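"""Daily intensity-difference trends and trajectory typing.

For each zone, the D-series (I-series) is the daily sum over its
decrease-mask (increase-mask) pixels of the difference between the 2020
layer and the matched previous-year baseline.  A fifth-order polynomial
fitted to each series — the D-line / I-line — summarises the trajectory;
cities whose fitted D-line has two interior local maxima are "M"-type (two
recovery phases), one maximum makes them "inverted_U" (a single recovery),
and the derivative sign at the window end gives the tail direction (up =
further recovery expected, down = relapse).
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial

from .rasters import RasterStack
from .zonemap import ZoneMap

__all__ = ["PolyFit", "daily_difference_series", "fit_polyline",
           "classify_trajectory", "zone_trends"]


def daily_difference_series(stack: RasterStack, baseline: np.ndarray,
                            zones: ZoneMap, decrease_mask: np.ndarray,
                            increase_mask: np.ndarray) -> pd.DataFrame:
    """Per-zone daily sums of (2020 − baseline) over fixed membership masks.

    The masks come from the period-aggregate comparison (e.g. a
    change-raster classification) and stay fixed across days.  Zones whose
    masks are empty get flat zero series and ``flagged=True``.
    """
    stack.grid.check_compatible(zones.grid)
    base = np.asarray(baseline, dtype=np.float64)
    if base.shape != stack.grid.shape:
        raise ValueError("baseline layer does not match the grid")
    diff = stack.data - base[None, :, :]
    rows = []
    for z in zones.zone_ids:
        zm = zones.mask(z)
        dm, im = zm & decrease_mask, zm & increase_mask
        d_series = np.nansum(diff[:, dm], axis=1) if dm.any() \
            else np.zeros(len(stack))
        i_series = np.nansum(diff[:, im], axis=1) if im.any() \
            else np.zeros(len(stack))
        flagged = not (dm.any() or im.any())
        for t, d in enumerate(stack.dates):
            rows.append((z, d.isoformat(), float(d_series[t]),
                         float(i_series[t]), flagged))
    return pd.DataFrame(rows, columns=["zone_id", "date", "d_value",
                                       "i_value", "flagged"])


@dataclass
class PolyFit:
    """A degree-5 least-squares fit on a standardized day index.

    ``poly`` carries the numpy Polynomial with its [-1, 1] window mapping;
    ``coef_raw`` are the equivalent coefficients in the natural day-index
    basis; ``r2`` is the coefficient of determination.
    """

    poly: Polynomial
    coef_raw: np.ndarray
    r2: float
    x_min: float
    x_max: float


def fit_polyline(x, y, degree: int = 5) -> PolyFit:
    """Fit a fifth-order polynomial trend line by least squares.

    The day index is mapped onto [-1, 1] before fitting for numerical
    conditioning.  Requires at least ``degree + 2`` observations.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) < degree + 2:
        raise ValueError(f"need ≥ {degree + 2} observations for a "
                         f"degree-{degree} trend")
    poly = Polynomial.fit(x, y, deg=degree)
    resid = y - poly(x)
    ss_res = float((resid ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res < 1e-12
                                                   else 0.0)
    return PolyFit(poly=poly, coef_raw=poly.convert().coef, r2=r2,
                   x_min=float(x.min()), x_max=float(x.max()))


def _interior_maxima(poly: Polynomial, lo: float, hi: float,
                     n_grid: int = 8193) -> list[float]:
    """Strict local maxima of the polynomial strictly inside (lo, hi).

    Found as +→− sign changes of the quartic derivative on a dense grid,
    refined by bisection; endpoint extrema are never counted.
    """
    from scipy.optimize import brentq

    der = poly.deriv()
    eps = (hi - lo) * 1e-9
    xs = np.linspace(lo + eps, hi - eps, n_grid)
    dv = der(xs)
    maxima = []
    for i in np.nonzero((dv[:-1] > 0) & (dv[1:] < 0))[0]:
        maxima.append(float(brentq(der, xs[i], xs[i + 1])))
    return maxima


def classify_trajectory(fit: PolyFit, window: tuple[float, float] | None = None
                        ) -> tuple[str, str, bool]:
    """Type a fitted D-line: ("M" | "inverted_U", "up" | "down", confident).

    Two interior maxima ⇒ M-type, one ⇒ inverted-U; any other count is
    mapped to the nearest class (≥ 2 ⇒ M, else inverted-U) with
    ``confident=False``.  Tail is the derivative sign at the window's right
    end; an exactly-zero derivative falls back to the second-derivative
    sign (also flagged non-confident).
    """
    lo, hi = window if window is not None else (fit.x_min, fit.x_max)
    if hi <= lo:
        raise ValueError("empty trajectory window")
    maxima = _interior_maxima(fit.poly, lo, hi)
    count = len(maxima)
    traj = "M" if count >= 2 else "inverted_U"
    confident = count in (1, 2)
    der = fit.poly.deriv()
    slope = float(der(hi))
    if slope == 0.0:
        slope = float(der.deriv()(hi))
        confident = False
    tail = "up" if slope > 0 else "down"
    return traj, tail, confident


def zone_trends(series: pd.DataFrame, degree: int = 5) -> pd.DataFrame:
    """Fit D- and I-lines per zone and classify the D-line trajectory.

    ``series`` is the long table from :func:`daily_difference_series`.
    """
    rows = []
    for z, grp in series.groupby("zone_id"):
        grp = grp.sort_values("date")
        days = pd.to_datetime(grp["date"])
        t = (days - days.iloc[0]).dt.days.to_numpy(dtype=float)
        d_fit = fit_polyline(t, grp["d_value"].to_numpy(), degree)
        i_fit = fit_polyline(t, grp["i_value"].to_numpy(), degree)
        traj, tail, confident = classify_trajectory(d_fit)
        rows.append((z, traj, tail, confident, d_fit.r2, i_fit.r2,
                     tuple(d_fit.coef_raw), tuple(i_fit.coef_raw)))
    return pd.DataFrame(rows, columns=["zone_id", "traj_type", "tail",
                                       "confident", "r2_d", "r2_i",
                                       "d_coef", "i_coef"])
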