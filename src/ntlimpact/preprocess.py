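"""Daily nighttime-light cleaning.

Three steps, in the order they are applied:

1. :func:`clamp_negatives` — sensor radiances below zero are set to 0.
2. :func:`filter_moonless` — dates contaminated by moonlight are dropped,
   either by an explicit date-window list (the default windows cover
   20 Jan–1 Feb, 16 Feb–2 Mar and 17 Mar–1 Apr 2020, i.e. roughly ±1 week
   around each new moon) or by an analytic lunar-phase-angle criterion.
3. :func:`smbq_repair` — per-pixel time-series outliers are detected with
   Tukey quartile fences (the "statistical method based on quartiles") and
   repaired by clipping to the fence: high spikes (scan-edge noise, fires)
   to Q3 + 1.5·IQR, low drops (cloud) to Q1 − 1.5·IQR.
"""
from __future__ import annotations

import datetime as dt
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rasters import RasterStack

__all__ = [
    "PAPER_MOONLESS_WINDOWS", "QuartileBounds", "OutlierMask",
    "clamp_negatives", "moon_phase_angle", "filter_moonless",
    "quartile_bounds", "smbq_repair", "preprocess_stack",
]

#: Default moonless windows (closed date intervals) for early 2020; each
#: spans roughly the half lunation centred on a new moon.
PAPER_MOONLESS_WINDOWS: tuple[tuple[dt.date, dt.date], ...] = (
    (dt.date(2020, 1, 20), dt.date(2020, 2, 1)),
    (dt.date(2020, 2, 16), dt.date(2020, 3, 2)),
    (dt.date(2020, 3, 17), dt.date(2020, 4, 1)),
)

FLAG_NONE, FLAG_HIGH, FLAG_LOW = 0, 1, 2


def clamp_negatives(stack: RasterStack) -> RasterStack:
    """Replace negative radiances with 0; NaN (nodata) passes through."""
    out = stack.copy()
    out.data = np.where(out.data < 0, 0.0, out.data)
    return out


# ---------------------------------------------------------------------------
# Lunar phase.  Low-precision analytic ephemeris: truncated series for the
# geocentric ecliptic longitudes of the Moon and Sun (accurate to a fraction
# of a degree over the supported range), from which the elongation and hence
# the phase angle follow.  Convention: phase angle 0° = full moon,
# 180° = new moon, so "angle > 90°" selects the dark half of the lunation.
# ---------------------------------------------------------------------------

def _julian_day(d: dt.date) -> float:
    # at 12:00 UT, the midpoint of the civil date
    y, m, day = d.year, d.month, d.day
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) \
        + day + b - 1524.5 + 0.5


def moon_phase_angle(date: dt.date) -> float:
    """Lunar phase angle in degrees for the given calendar date.

    0° at full moon, 180° at new moon.  Valid for roughly 1900–2100; the
    truncated series degrades outside that range.
    """
    if isinstance(date, str):
        date = dt.date.fromisoformat(date)
    if not dt.date(1900, 1, 1) <= date <= dt.date(2100, 1, 1):
        raise ValueError(f"date {date} outside supported ephemeris range")
    t = (_julian_day(date) - 2451545.0) / 36525.0
    s = lambda deg: math.sin(math.radians(deg % 360.0))

    lam_moon = (218.32 + 481267.881 * t
                + 6.29 * s(135.0 + 477198.87 * t)
                - 1.27 * s(259.3 - 413335.36 * t)
                + 0.66 * s(235.7 + 890534.22 * t)
                + 0.21 * s(269.9 + 954397.74 * t)
                - 0.19 * s(357.5 + 35999.05 * t)
                - 0.11 * s(186.5 + 966404.03 * t))
    g = 357.528 + 35999.050 * t
    lam_sun = 280.460 + 36000.770 * t + 1.915 * s(g) + 0.020 * s(2 * g)

    elong = (lam_moon - lam_sun) % 360.0
    separation = min(elong, 360.0 - elong)  # in [0, 180]
    return 180.0 - separation


def filter_moonless(stack: RasterStack, mode: str = "explicit",
                    dates=None, threshold: float = 90.0) -> RasterStack:
    """Retain only moonless dates.

    Parameters
    ----------
    mode : {"explicit", "ephemeris", "all"}
        "explicit" keeps dates inside closed windows (``dates`` as a list of
        (start, end) pairs or of individual dates; defaults to
        :data:`PAPER_MOONLESS_WINDOWS`).  "ephemeris" keeps dates whose
        phase angle exceeds ``threshold`` degrees.  "all" keeps everything.
    """
    if mode == "all":
        keep = np.ones(len(stack), dtype=bool)
    elif mode == "explicit":
        windows = PAPER_MOONLESS_WINDOWS if dates is None else list(dates)
        if windows and not isinstance(windows[0], tuple):
            explicit = {dt.date.fromisoformat(d) if isinstance(d, str) else d
                        for d in windows}
            keep = np.array([d in explicit for d in stack.dates])
        else:
            keep = np.array([any(a <= d <= b for a, b in windows)
                             for d in stack.dates])
    elif mode == "ephemeris":
        keep = np.array([moon_phase_angle(d) > threshold
                         for d in stack.dates])
    else:
        raise ValueError(f"unknown moonless mode {mode!r}")
    if not keep.any():
        warnings.warn("moonless filtering removed every date", stacklevel=2)
    out = stack.select(keep)
    out.moonlit = np.zeros(len(out), dtype=bool)
    return out


# ---------------------------------------------------------------------------
# Quartile-fence outlier detection and repair.
# ---------------------------------------------------------------------------

@dataclass
class QuartileBounds:
    """Per-pixel quartiles and Tukey fences over the date axis.

    Quartiles use linear interpolation between order statistics.  Pixels
    with fewer than 4 finite observations are flagged ``unprocessable`` and
    passed through unrepaired.
    """

    q1: np.ndarray
    q3: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    unprocessable: np.ndarray

    MIN_OBS = 4


def quartile_bounds(values: np.ndarray) -> QuartileBounds:
    """Fences for a single series (1-D) or a stack array (dates first axis)."""
    values = np.asarray(values, dtype=np.float64)
    arr = values[:, None] if values.ndim == 1 else values
    finite = np.isfinite(arr).sum(axis=0)
    unprocessable = finite < QuartileBounds.MIN_OBS
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        q1 = np.nanpercentile(arr, 25, axis=0, method="linear")
        q3 = np.nanpercentile(arr, 75, axis=0, method="linear")
    q1 = np.where(unprocessable, np.nan, q1)
    q3 = np.where(unprocessable, np.nan, q3)
    iqr = q3 - q1
    bounds = QuartileBounds(q1, q3, q1 - 1.5 * iqr, q3 + 1.5 * iqr,
                            unprocessable)
    if values.ndim == 1:
        for name in ("q1", "q3", "lower", "upper", "unprocessable"):
            setattr(bounds, name, getattr(bounds, name)[0])
    return bounds


@dataclass
class OutlierMask:
    """Per-pixel-day outlier flags (0 none, 1 high, 2 low) with summaries."""

    flags: np.ndarray          # int8, same shape as the stack data
    unprocessable: np.ndarray  # 2-D bool, pixels passed through unrepaired

    def counts(self, dates) -> pd.DataFrame:
        n_high = (self.flags == FLAG_HIGH).sum(axis=(1, 2))
        n_low = (self.flags == FLAG_LOW).sum(axis=(1, 2))
        return pd.DataFrame({"date": [d.isoformat() for d in dates],
                             "n_high": n_high, "n_low": n_low})


def smbq_repair(stack: RasterStack) -> tuple[RasterStack, OutlierMask]:
    """Detect and repair per-pixel time-series outliers by quartile fences.

    A value above ``Q3 + 1.5·IQR`` is replaced by that fence; a value below
    ``Q1 − 1.5·IQR`` by the lower fence.  Non-outliers and NaN are
    unchanged; pixels with fewer than 4 finite observations pass through.
    Clipping preserves the order statistics that define the fences, so a
    second application is a no-op.
    """
    bounds = quartile_bounds(stack.data)
    data = stack.data
    with np.errstate(invalid="ignore"):
        high = data > bounds.upper[None, :, :]
        low = data < bounds.lower[None, :, :]
    high &= ~bounds.unprocessable[None, :, :]
    low &= ~bounds.unprocessable[None, :, :]
    flags = np.zeros(data.shape, dtype=np.int8)
    flags[high] = FLAG_HIGH
    flags[low] = FLAG_LOW
    repaired = data.copy()
    repaired[high] = np.broadcast_to(bounds.upper, data.shape)[high]
    repaired[low] = np.broadcast_to(bounds.lower, data.shape)[low]
    out = stack.copy()
    out.data = repaired
    return out, OutlierMask(flags, bounds.unprocessable)


def preprocess_stack(stack: RasterStack, moonless_mode: str = "explicit",
                     moonless_dates=None, threshold: float = 90.0
                     ) -> tuple[RasterStack, OutlierMask]:
    """Full cleaning chain: clamp → moonless filter → quartile repair."""
    stack = clamp_negatives(stack)
    stack = filter_moonless(stack, mode=moonless_mode, dates=moonless_dates,
                            threshold=threshold)
    return smbq_repair(stack)
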