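"""Seeded synthetic inputs with planted ground truth.

Generates everything the pipeline consumes — baseline and analysis-year
radiance stacks, a zone map, case tables and mobility series — from a single
:class:`SceneConfig`, recording the planted truth (clean radiance, injected
outliers, per-zone suppression, trajectory types) so every downstream stage
can be validated without real satellite downloads.

The statistical structure emulates daily low-light imagery of urban areas:

* dark rural pixels fluctuate in a configurable range (default 0–1 nW/cm²/sr);
* each city is a bright core at its central business district whose radiance
  decays exponentially outward;
* sparse high spikes (fires, scan-edge noise) outnumber low drops (cloud);
* the analysis year carries an additive development increment over the
  baseline year;
* an epidemic multiplicatively dims the lit pixels of each zone by a
  time-varying suppression factor s(t) ∈ (0, 1], with s = 1 outside the
  epidemic window.
"""
from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as P

from .rasters import Grid, RasterStack
from .zonemap import ZoneMap
from .preprocess import PAPER_MOONLESS_WINDOWS, FLAG_HIGH, FLAG_LOW
from .recovery import match_lunar_dates

__all__ = [
    "SuppressionProfile", "trajectory_profile", "ZoneSpec", "NoiseConfig",
    "LogisticCases", "SceneConfig", "GroundTruth", "default_scene_config",
    "make_scene", "make_case_table", "make_mobility_series",
]


# ---------------------------------------------------------------------------
# Suppression profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SuppressionProfile:
    """Per-zone epidemic dimming factor s(t) ∈ (0, 1]; s = 1 outside window.

    Kinds
    -----
    constant : s = s_min throughout the window.
    trough   : piecewise-linear dip to s_min at the window midpoint.
    poly     : s follows a quintic recovery curve with a planted trajectory
               type ("M" = two interior recovery peaks, "inverted_U" = one)
               and tail direction at the window end; build these with
               :func:`trajectory_profile`.
    """

    start: dt.date
    end: dt.date
    s_min: float = 0.5
    kind: str = "trough"
    poly_coef: tuple = ()        # quintic in u = (t-start)/(end-start)
    traj_type: str | None = None
    tail: str | None = None

    def __post_init__(self):
        if not 0 < self.s_min <= 1:
            raise ValueError("s_min must lie in (0, 1]")
        if self.end <= self.start:
            raise ValueError("suppression window must be nonempty")
        if self.kind not in ("constant", "trough", "poly"):
            raise ValueError(f"unknown suppression kind {self.kind!r}")

    def factor(self, date: dt.date) -> float:
        if not self.start <= date <= self.end:
            return 1.0
        u = (date - self.start).days / (self.end - self.start).days
        if self.kind == "constant":
            return self.s_min
        if self.kind == "trough":
            return 1.0 - (1.0 - self.s_min) * (1.0 - abs(2.0 * u - 1.0))
        return float(P.polyval(u, np.asarray(self.poly_coef)))


def trajectory_profile(start: dt.date, end: dt.date, traj_type: str,
                       tail: str, s_min: float, rng: np.random.Generator
                       ) -> SuppressionProfile:
    """Plant a quintic suppression curve with a known trajectory shape.

    The quintic's quartic derivative is built from explicit roots, so the
    number of interior local maxima (2 for "M", 1 for "inverted_U") and the
    derivative sign at the window end ("up"/"down") hold by construction.
    """
    if traj_type not in ("M", "inverted_U"):
        raise ValueError(f"unknown trajectory type {traj_type!r}")
    if tail not in ("up", "down"):
        raise ValueError(f"unknown tail direction {tail!r}")
    k = 1.0 if tail == "up" else -1.0
    if traj_type == "M":
        # four interior critical points; sign of k selects which pair are maxima
        while True:
            roots = np.sort(rng.uniform(0.10, 0.90, size=4))
            if np.diff(roots).min() >= 0.12:
                break
        deriv = k * P.polyfromroots(roots)
    else:
        while True:
            roots = np.sort(rng.uniform(0.15, 0.85, size=2))
            if roots[1] - roots[0] >= 0.25:
                break
        a = rng.uniform(1.3, 2.0)       # complex-pair factor: no real roots
        b = rng.uniform(0.3, 0.8)
        deriv = k * P.polymul(P.polyfromroots(roots),
                              np.array([a * a + b * b, -2 * a, 1.0]))
    quintic = P.polyint(deriv)
    crit = P.polyroots(deriv)
    crit = crit[np.abs(crit.imag) < 1e-12].real
    crit = crit[(crit > 0.0) & (crit < 1.0)]
    vals = P.polyval(np.concatenate(([0.0, 1.0], crit)), quintic)
    lo, hi = vals.min(), vals.max()   # exact extrema on [0, 1]
    # affine map onto [s_min, 1]: s(u) = s_min + (1-s_min)(q(u) - lo)/(hi - lo)
    scaled = np.zeros(6)
    scaled[: len(quintic)] = quintic
    scaled = scaled * ((1.0 - s_min) / (hi - lo))
    scaled[0] += s_min - (1.0 - s_min) * lo / (hi - lo)
    return SuppressionProfile(start, end, s_min=s_min, kind="poly",
                              poly_coef=tuple(scaled),
                              traj_type=traj_type, tail=tail)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZoneSpec:
    """One city: a bright CBD core with exponential outward decay.

    ``hospital_pixels`` mark epidemic-response sites (hospitals, checkpoints)
    that brighten by ``hospital_boost`` during the zone's suppression window
    instead of dimming — the one land-use class whose activity rises in an
    outbreak.
    """

    zone_id: int
    center: tuple[int, int]            # (row, col) of the CBD pixel
    peak: float = 50.0                 # CBD radiance, nW/cm²/sr
    decay: float = 6.0                 # e-folding distance, pixels
    suppression: SuppressionProfile | None = None
    hospital_pixels: tuple[tuple[int, int], ...] = ()
    hospital_boost: float = 1.6


@dataclass(frozen=True)
class NoiseConfig:
    """Perturbations applied to clean analysis-year layers.

    ``spike_rate`` / ``cloud_drop_rate`` are per pixel-day probabilities;
    spikes multiply the clean value by a lognormal factor (median
    ``spike_median``), cloud drops multiply the observed value by
    U(0, 0.2).  Dark pixels redraw uniformly from ``dark_range`` each day.
    """

    dark_range: tuple[float, float] = (0.0, 1.0)
    dark_fluctuation: bool = True
    spike_rate: float = 0.002
    spike_median: float = 10.0
    spike_sigma: float = 0.5
    cloud_drop_rate: float = 0.001
    mobility_sigma: float = 0.05

    def __post_init__(self):
        if not 0 <= self.spike_rate <= 1 or not 0 <= self.cloud_drop_rate <= 1:
            raise ValueError("spike/cloud rates must lie in [0, 1]")
        if self.spike_rate + self.cloud_drop_rate > 1:
            raise ValueError("spike_rate + cloud_drop_rate must be ≤ 1")

    @classmethod
    def none(cls) -> "NoiseConfig":
        return cls(dark_fluctuation=False, spike_rate=0.0,
                   cloud_drop_rate=0.0, mobility_sigma=0.0)


@dataclass(frozen=True)
class LogisticCases:
    """Cumulative confirmed cases follow a logistic K/(1+e^{-r(t-t0)})."""

    k: float
    rate: float = 0.25
    midpoint: dt.date = dt.date(2020, 2, 5)
    cure_lag: int = 14
    cure_frac: float = 0.90
    death_frac: float = 0.04


def _daterange(start: dt.date, end: dt.date) -> tuple[dt.date, ...]:
    n = (end - start).days + 1
    return tuple(start + dt.timedelta(days=i) for i in range(n))


@dataclass(frozen=True)
class SceneConfig:
    """Everything needed to generate one deterministic synthetic study."""

    grid: Grid = Grid(100, 100, 500.0)
    zones: tuple[ZoneSpec, ...] = ()
    dates: tuple[dt.date, ...] = field(
        default_factory=lambda: _daterange(dt.date(2020, 1, 20),
                                           dt.date(2020, 3, 31)))
    development_increment: float = 0.3   # additive, analysis year, lit pixels
    noise: NoiseConfig = NoiseConfig()
    epidemic: tuple[tuple[int, LogisticCases], ...] = ()
    lunar_offset: int = 12               # 2020 → 2019 matched-date shift
    moonlit_dates: tuple[dt.date, ...] | None = None   # None → outside the
    seed: int = 0                        # default moonless windows

    def __post_init__(self):
        ids = [z.zone_id for z in self.zones]
        if len(set(ids)) != len(ids):
            raise ValueError("zone ids must be unique")
        centers = [z.center for z in self.zones]
        if len(set(centers)) != len(centers):
            raise ValueError("overlapping zone centers")
        for z in self.zones:
            if z.decay <= 0:
                raise ValueError(f"zone {z.zone_id}: decay must be positive")
            r, c = z.center
            if not (0 <= r < self.grid.rows and 0 <= c < self.grid.cols):
                raise ValueError(f"zone {z.zone_id} does not fit on the grid")
            for (hr, hc) in z.hospital_pixels:
                if not (0 <= hr < self.grid.rows
                        and 0 <= hc < self.grid.cols):
                    raise ValueError(
                        f"zone {z.zone_id}: hospital pixel off the grid")
            if z.hospital_boost <= 1:
                raise ValueError("hospital_boost must exceed 1")

    def moonlit_flags(self) -> np.ndarray:
        if self.moonlit_dates is not None:
            lit = set(self.moonlit_dates)
            return np.array([d in lit for d in self.dates])
        return np.array([not any(a <= d <= b
                                 for a, b in PAPER_MOONLESS_WINDOWS)
                         for d in self.dates])


def default_scene_config(seed: int = 0, n_zones: int = 6,
                         grid: Grid = Grid(100, 100, 500.0),
                         suppression_kind: str = "trough") -> SceneConfig:
    """A six-city scene with graded epidemic severity.

    Suppression depths span 0.35–0.9 across zones so severity ranking is
    well defined; the epidemic window covers the outbreak and recovery
    periods (23 Jan – 31 Mar 2020).
    """
    rng = np.random.default_rng([seed, 101])
    rows, cols = grid.rows, grid.cols
    # CBD centers on a jittered lattice so zones tile the grid
    side = math.ceil(math.sqrt(n_zones))
    centers = []
    for i in range(n_zones):
        r = int((i // side + 0.5) / side * rows + rng.integers(-rows // 10,
                                                              rows // 10 + 1))
        c = int((i % side + 0.5) / side * cols + rng.integers(-cols // 10,
                                                              cols // 10 + 1))
        centers.append((min(max(r, 1), rows - 2), min(max(c, 1), cols - 2)))
    window = (dt.date(2020, 1, 23), dt.date(2020, 3, 31))
    s_mins = np.linspace(0.35, 0.90, n_zones)
    zones = []
    for i, (ctr, s_min) in enumerate(zip(centers, s_mins), start=1):
        prof = SuppressionProfile(*window, s_min=float(s_min),
                                  kind=suppression_kind)
        hospitals = ((min(ctr[0] + 2, rows - 1), min(ctr[1] + 2, cols - 1)),
                     (max(ctr[0] - 2, 0), min(ctr[1] + 1, cols - 1)))
        zones.append(ZoneSpec(zone_id=i, center=ctr,
                              peak=float(rng.uniform(30, 60)),
                              decay=float(rng.uniform(4, 8)),
                              suppression=prof,
                              hospital_pixels=hospitals))
    epidemic = tuple(
        (z.zone_id, LogisticCases(k=float(np.round(2000 * (1 - s)) * 10),
                                  rate=0.25, midpoint=dt.date(2020, 2, 5)))
        for z, s in zip(zones, s_mins))
    return SceneConfig(grid=grid, zones=tuple(zones), epidemic=epidemic,
                       seed=seed)


# ---------------------------------------------------------------------------
# Scene assembly
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Planted truth for a generated scene.

    ``clean`` holds the noise-free analysis-year layers; ``outlier_flags``
    marks every injected perturbation (1 high spike, 2 low drop) exactly
    once; ``unsuppressed`` is the analysis-year radiance the scene would
    have had with no epidemic (baseline + development on lit pixels).
    """

    clean: np.ndarray
    outlier_flags: np.ndarray
    suppression: pd.DataFrame          # zone_id, date, s
    trajectory: pd.DataFrame           # zone_id, traj_type, tail
    development: np.ndarray            # 2-D additive increment actually applied
    unsuppressed: np.ndarray           # 2-D no-epidemic analysis radiance
    lit: np.ndarray                    # 2-D bool, pixels subject to suppression

    def deficit_totals(self, zonemap: ZoneMap) -> pd.Series:
        """Planted radiance deficit Σ (unsuppressed − clean) per zone."""
        diff = self.unsuppressed[None, :, :] - self.clean
        out = {}
        for z in zonemap.zone_ids:
            m = zonemap.mask(z)
            out[z] = float(diff[:, m].sum())
        return pd.Series(out, name="deficit")


def _radiance_field(config: SceneConfig) -> tuple[np.ndarray, np.ndarray,
                                                  np.ndarray]:
    """Return (baseline field, zone labels, lit mask)."""
    rows, cols = config.grid.shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    dark_floor = 0.5 * (config.noise.dark_range[0]
                        + config.noise.dark_range[1])
    contrib = np.zeros((len(config.zones), rows, cols))
    for i, z in enumerate(config.zones):
        dist = np.hypot(rr - z.center[0], cc - z.center[1])
        contrib[i] = z.peak * np.exp(-dist / z.decay)
    if len(config.zones):
        base = contrib.sum(axis=0) + dark_floor
        labels = np.array([z.zone_id for z in config.zones])[
            np.argmin([np.hypot(rr - z.center[0], cc - z.center[1])
                       for z in config.zones], axis=0)]
        lit = contrib.sum(axis=0) > config.noise.dark_range[1]
    else:
        base = np.full((rows, cols), dark_floor)
        labels = np.zeros((rows, cols), dtype=np.int32)
        lit = np.zeros((rows, cols), dtype=bool)
    return base, labels.astype(np.int32), lit


def make_scene(config: SceneConfig
               ) -> tuple[RasterStack, RasterStack, ZoneMap, GroundTruth]:
    """Generate (baseline stack, analysis stack, zone map, ground truth).

    The baseline stack holds the composite-like previous-year field on the
    lunar-matched dates; the analysis stack is the daily epidemic-year
    imagery with development growth, suppression, and injected noise.
    """
    rng = np.random.default_rng([int(config.seed), 7])
    base, labels, lit = _radiance_field(config)
    zonemap = ZoneMap(labels, config.grid)
    dark_floor = 0.5 * (config.noise.dark_range[0]
                        + config.noise.dark_range[1])

    unsuppressed = base.copy()
    unsuppressed[lit] = base[lit] + config.development_increment
    development = np.where(lit, float(config.development_increment), 0.0)

    n = len(config.dates)
    sfac = np.ones((n, len(config.zones)))
    for j, z in enumerate(config.zones):
        if z.suppression is not None:
            sfac[:, j] = [z.suppression.factor(d) for d in config.dates]
    s_pixel = np.ones((n, *config.grid.shape))
    for j, z in enumerate(config.zones):
        zm = labels == z.zone_id
        s_pixel[:, zm] = sfac[:, j][:, None]

    clean = np.broadcast_to(base, (n, *base.shape)).copy()
    clean[:, lit] = unsuppressed[lit][None, :] * s_pixel[:, lit]
    for z in config.zones:
        if not z.hospital_pixels or z.suppression is None:
            continue
        active = np.array([z.suppression.start <= d <= z.suppression.end
                           for d in config.dates])
        for (hr, hc) in z.hospital_pixels:
            clean[active, hr, hc] = unsuppressed[hr, hc] * z.hospital_boost
            clean[~active, hr, hc] = unsuppressed[hr, hc]

    data = clean.copy()
    noise = config.noise
    if noise.dark_fluctuation:
        dark = ~lit
        data[:, dark] = rng.uniform(*noise.dark_range,
                                    size=(n, int(dark.sum())))
    u = rng.random(data.shape)
    spike = u < noise.spike_rate
    drop = (u >= noise.spike_rate) & (u < noise.spike_rate
                                      + noise.cloud_drop_rate)
    factors = rng.lognormal(mean=math.log(noise.spike_median),
                            sigma=noise.spike_sigma, size=int(spike.sum()))
    data[spike] = np.maximum(clean[spike], dark_floor) * factors
    data[drop] = data[drop] * rng.uniform(0.0, 0.2, size=int(drop.sum()))
    flags = np.zeros(data.shape, dtype=np.int8)
    flags[spike] = FLAG_HIGH
    flags[drop] = FLAG_LOW

    analysis = RasterStack(config.dates, data, config.grid,
                           config.moonlit_flags())
    # composite-like baseline covering the continuous matched 2019 range
    m0 = match_lunar_dates(config.dates[0], offset_days=config.lunar_offset)
    m1 = match_lunar_dates(config.dates[-1], offset_days=config.lunar_offset)
    matched = _daterange(m0, m1)
    baseline = RasterStack(
        matched, np.broadcast_to(base, (len(matched), *base.shape)).copy(),
        config.grid)

    supp = pd.DataFrame(
        [(z.zone_id, d.isoformat(), sfac[i, j])
         for j, z in enumerate(config.zones)
         for i, d in enumerate(config.dates)],
        columns=["zone_id", "date", "s"])
    traj = pd.DataFrame(
        [(z.zone_id, z.suppression.traj_type, z.suppression.tail)
         for z in config.zones
         if z.suppression is not None and z.suppression.kind == "poly"],
        columns=["zone_id", "traj_type", "tail"])
    truth = GroundTruth(clean=clean, outlier_flags=flags, suppression=supp,
                        trajectory=traj, development=development,
                        unsuppressed=unsuppressed, lit=lit)
    return baseline, analysis, zonemap, truth


# ---------------------------------------------------------------------------
# Tabular inputs
# ---------------------------------------------------------------------------

def make_case_table(config: SceneConfig) -> pd.DataFrame:
    """Daily cumulative case counts per zone (confirmed/suspected/cured/dead).

    Counts follow the zone's logistic curve; cured and dead lag confirmed
    by ``cure_lag`` days with fixed fractions, so cured + dead ≤ confirmed
    on every date and all cumulative series are nondecreasing.  Zones with
    no epidemic parameters report zeros.
    """
    params = dict(config.epidemic)
    rows = []
    for z in config.zones:
        p = params.get(z.zone_id)
        for d in config.dates:
            if p is None:
                rows.append((z.zone_id, d.isoformat(), 0, 0, 0, 0))
                continue
            def logistic(day: dt.date) -> int:
                x = p.rate * (day - p.midpoint).days
                return int(round(p.k / (1.0 + math.exp(-x))))
            con = logistic(d)
            lagged = logistic(d - dt.timedelta(days=p.cure_lag))
            cured = int(math.floor(p.cure_frac * lagged))
            dead = int(math.floor(p.death_frac * lagged))
            prev = logistic(d - dt.timedelta(days=7))
            suspected = int(round(0.25 * max(con - prev, 0)))
            rows.append((z.zone_id, d.isoformat(), con, suspected,
                         cured, dead))
    return pd.DataFrame(rows, columns=["zone_id", "date", "confirmed",
                                       "suspected", "cured", "dead"])


def _weekly(d: dt.date) -> float:
    return 1.0 + 0.15 * math.sin(2.0 * math.pi * d.toordinal() / 7.0)


def make_mobility_series(config: SceneConfig) -> pd.DataFrame:
    """Intra-city travel-intensity series for both years.

    The analysis-year value is the zone's seasonal baseline times its
    suppression factor times multiplicative noise; the matched baseline-year
    date carries the same seasonal phase (travel rhythms align with the
    lunar festival calendar), so with noise off the daily recovery ratio
    equals s(t) exactly.
    """
    rng = np.random.default_rng([int(config.seed), 23])
    sigma = config.noise.mobility_sigma
    rows = []
    for z in config.zones:
        level = 3.0 + 0.02 * z.peak        # resident-travel baseline level
        for d in config.dates:
            s = z.suppression.factor(d) if z.suppression else 1.0
            eps = math.exp(sigma * rng.standard_normal()) if sigma else 1.0
            base_val = level * _weekly(d)
            matched = match_lunar_dates(d, offset_days=config.lunar_offset)
            rows.append((z.zone_id, matched.isoformat(), base_val))
            rows.append((z.zone_id, d.isoformat(), base_val * s * eps))
    return (pd.DataFrame(rows, columns=["zone_id", "date", "iict"])
            .drop_duplicates(subset=["zone_id", "date"], keep="first")
            .sort_values(["zone_id", "date"]).reset_index(drop=True))
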