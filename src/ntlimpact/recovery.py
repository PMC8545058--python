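"""Recovery-degree estimation against a lunar-calendar-matched baseline.

A zone's recovery degree over a window is

    RNTL = Σ R′_i / Σ r′_i

— summed 2020 radiance over the window's retained dates and pixels divided
by the matched 2019 radiance.  RNTL ≥ 1 means fully recovered.  The
matched 2019 dates occupy the same position relative to the Chinese New
Year, so Spring-Festival effects cancel.  The independent mobility check is
the daily intra-city travel-intensity ratio m = P_j / p_j, aggregated over
the same window, and the two are compared in a banded cross-tabulation.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rasters import RasterStack
from .zonemap import ZoneMap

__all__ = [
    "CHINESE_NEW_YEAR", "PeriodSpec", "DEFAULT_PERIODS", "match_lunar_dates",
    "rntl", "iict_recovery", "period_iict_recovery", "recovery_crosstab",
    "agreement_fraction", "d_value",
]

#: Chinese New Year dates used by the table matching mode.
CHINESE_NEW_YEAR = {2019: dt.date(2019, 2, 5), 2020: dt.date(2020, 1, 25)}


def match_lunar_dates(date_2020: dt.date, mode: str = "offset",
                      offset_days: int = 12) -> dt.date:
    """Map an analysis-year date to its lunar-matched baseline-year date.

    mode="offset" (default) shifts to the previous year plus a fixed
    ``offset_days`` (default +12, pairing 1 Mar 2020 with 13 Mar 2019).
    mode="table" anchors both years at their Chinese New Year, pairing
    dates at equal displacement from the festival (25 Jan 2020 ↔
    5 Feb 2019).
    """
    if isinstance(date_2020, str):
        date_2020 = dt.date.fromisoformat(date_2020)
    if mode == "offset":
        try:
            anniversary = date_2020.replace(year=date_2020.year - 1)
        except ValueError:                      # 29 Feb in a leap year
            anniversary = dt.date(date_2020.year - 1, 2, 28)
        return anniversary + dt.timedelta(days=offset_days)
    if mode == "table":
        year = date_2020.year
        if year not in CHINESE_NEW_YEAR or year - 1 not in CHINESE_NEW_YEAR:
            raise ValueError(f"no lunar correspondence table for {year}")
        return CHINESE_NEW_YEAR[year - 1] \
            + (date_2020 - CHINESE_NEW_YEAR[year])
    raise ValueError(f"unknown lunar matching mode {mode!r}")


@dataclass(frozen=True)
class PeriodSpec:
    """A named analysis window and its matched baseline window."""

    name: str
    start: dt.date
    end: dt.date
    matched_start: dt.date
    matched_end: dt.date
    role: str = "recovery"

    def contains(self, d: dt.date) -> bool:
        return self.start <= d <= self.end

    def matched_contains(self, d: dt.date) -> bool:
        return self.matched_start <= d <= self.matched_end


#: Default study periods: outbreak S1, whole recovery S2, and the February
#: and March recovery windows with their lunar-matched 2019 counterparts.
DEFAULT_PERIODS = {
    "S1": PeriodSpec("S1", dt.date(2020, 1, 23), dt.date(2020, 2, 18),
                     dt.date(2019, 2, 4), dt.date(2019, 3, 2),
                     role="outbreak"),
    "S2": PeriodSpec("S2", dt.date(2020, 2, 19), dt.date(2020, 3, 31),
                     dt.date(2019, 3, 3), dt.date(2019, 4, 12),
                     role="recovery"),
    "feb": PeriodSpec("feb", dt.date(2020, 2, 19), dt.date(2020, 2, 29),
                      dt.date(2019, 3, 3), dt.date(2019, 3, 12),
                      role="feb-recovery"),
    "mar": PeriodSpec("mar", dt.date(2020, 3, 1), dt.date(2020, 3, 31),
                      dt.date(2019, 3, 13), dt.date(2019, 4, 12),
                      role="mar-recovery"),
}


def rntl(stack_2020: RasterStack, stack_2019: RasterStack, zones: ZoneMap,
         normalize_by_days: bool = False) -> pd.DataFrame:
    """Per-zone recovery degree RNTL = Σ 2020 radiance / Σ matched 2019.

    Sums run over all pixels of the zone and all dates of each stack
    (callers subset the stacks to the period first).  Windows of unequal
    length are allowed — the statistic is a ratio of raw sums — unless
    ``normalize_by_days`` divides each side by its day count.  A zone whose
    denominator is not positive is flagged with RNTL NaN.
    """
    if len(stack_2020) == 0 or len(stack_2019) == 0:
        raise ValueError("both period stacks must be nonempty")
    stack_2020.grid.check_compatible(stack_2019.grid)
    stack_2020.grid.check_compatible(zones.grid)
    rows = []
    for z in zones.zone_ids:
        m = zones.mask(z)
        num = float(np.nansum(stack_2020.data[:, m]))
        den = float(np.nansum(stack_2019.data[:, m]))
        if normalize_by_days:
            num /= len(stack_2020)
            den /= len(stack_2019)
        if den > 0:
            rows.append((z, num / den, num, den, False))
        else:
            rows.append((z, np.nan, num, den, True))
    return pd.DataFrame(rows, columns=["zone_id", "rntl", "numerator",
                                       "denominator", "flagged"])


def iict_recovery(p_2020, p_2019):
    """Daily mobility recovery ratio m = P_j / p_j (elementwise).

    Non-positive baseline values yield NaN (flagged undefined).
    """
    p = np.asarray(p_2020, dtype=np.float64)
    q = np.asarray(p_2019, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(q > 0, p / q, np.nan)
    return m if m.ndim else float(m)


def period_iict_recovery(mobility: pd.DataFrame, period: PeriodSpec,
                         match_mode: str = "offset",
                         offset_days: int = 12) -> pd.DataFrame:
    """Period-level m per zone: the mean of daily ratios over the window.

    ``mobility`` must contain (zone_id, date, iict) rows covering both the
    2020 window and the matched 2019 dates.
    """
    t = mobility.assign(date=pd.to_datetime(mobility["date"]).dt.date)
    lookup = {(r.zone_id, r.date): r.iict for r in t.itertuples()}
    rows = []
    for z in sorted(t["zone_id"].unique()):
        ratios = []
        d = period.start
        while d <= period.end:
            matched = match_lunar_dates(d, mode=match_mode,
                                        offset_days=offset_days)
            p, q = lookup.get((z, d)), lookup.get((z, matched))
            if p is not None and q is not None:
                ratios.append(iict_recovery(p, q))
            d += dt.timedelta(days=1)
        ratios = [r for r in ratios if np.isfinite(r)]
        rows.append((z, float(np.mean(ratios)) if ratios else np.nan,
                     len(ratios)))
    return pd.DataFrame(rows, columns=["zone_id", "m", "n_days"])


DEFAULT_RECOVERY_BINS = (0.3, 0.6, 0.8, 1.0)


def _bin_labels(edges) -> list[str]:
    labels = [f"[{a:g},{b:g})" for a, b in zip(edges, edges[1:])]
    labels.append(f"[{edges[-1]:g},inf)")
    return labels


def recovery_crosstab(rntl_table: pd.DataFrame, m_table: pd.DataFrame,
                      edges=DEFAULT_RECOVERY_BINS
                      ) -> tuple[pd.DataFrame, list]:
    """Contingency counts of zones per (radiance bin × mobility bin).

    Bins are left-closed, the last open to +∞.  Zones present in only one
    table (or with undefined values) are excluded and returned.
    """
    a = rntl_table.set_index("zone_id")["rntl"]
    b = m_table.set_index("zone_id")["m"]
    common = a.index.intersection(b.index)
    excluded = sorted(set(a.index).symmetric_difference(b.index))
    a, b = a.loc[common], b.loc[common]
    bad = ~(np.isfinite(a) & np.isfinite(b)) \
        | (a < edges[0]) | (b < edges[0])
    excluded += sorted(common[bad])
    a, b = a[~bad], b[~bad]
    if len(a) == 0:
        raise ValueError("no zones common to both recovery tables")
    bins = list(edges) + [np.inf]
    labels = _bin_labels(edges)
    ab = pd.cut(a, bins=bins, labels=labels, right=False)
    bb = pd.cut(b, bins=bins, labels=labels, right=False)
    tab = pd.crosstab(ab, bb, dropna=False)
    tab.index.name, tab.columns.name = "ntl_bin", "iict_bin"
    return tab, excluded


def agreement_fraction(rntl_table: pd.DataFrame, m_table: pd.DataFrame,
                       threshold: float = 0.6) -> float:
    """Among zones whose radiance recovery exceeds ``threshold``, the
    fraction whose mobility recovery also does."""
    a = rntl_table.set_index("zone_id")["rntl"]
    b = m_table.set_index("zone_id")["m"]
    common = a.index.intersection(b.index)
    a, b = a.loc[common], b.loc[common]
    above = a > threshold
    if int(above.sum()) == 0:
        return np.nan
    return float(((a > threshold) & (b > threshold)).sum() / above.sum())


def d_value(rntl_mar: pd.DataFrame, rntl_feb: pd.DataFrame) -> pd.DataFrame:
    """March-minus-February recovery difference per zone.

    Negative values indicate fluctuating recovery (a March relapse); zones
    missing from either period are omitted.
    """
    a = rntl_mar.set_index("zone_id")["rntl"]
    b = rntl_feb.set_index("zone_id")["rntl"]
    common = a.index.intersection(b.index)
    out = (a.loc[common] - b.loc[common]).rename("d_value").reset_index()
    return out
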