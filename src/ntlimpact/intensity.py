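"""Zone-level influence intensity, five-level grading, and LISA clusters.

The influence intensity of a zone is SCNTL = Σ CNTL_i over its classified
(decrease ∪ increase) pixels — the more negative, the more affected.  Zones
are graded into five severity levels (I most severe … V least) by Jenks
natural breaks or a preset break table, and typed into HH/HL/LH/LL spatial
clusters with the Anselin Local Moran's I under inverse-distance weights
and conditional permutation inference.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .change import ChangeRaster
from .zonemap import ZoneMap

__all__ = ["PAPER_BREAKS", "ROMAN_LEVELS", "scntl", "jenks_breaks",
           "classify_level", "local_moran"]

#: Preset five-level break edges (nW/cm²/sr) from a national-scale analysis:
#: level I spans [−240000, −150000], II (−150000, −60000], III (−60000,
#: −30000], IV (−30000, −10000], V (−10000, 0].
PAPER_BREAKS: tuple[float, ...] = (-240_000.0, -150_000.0, -60_000.0,
                                   -30_000.0, -10_000.0, 0.0)

ROMAN_LEVELS = {1: "I", 2: "II", 3: "III", 4: "IV", 5: "V"}


def scntl(change: ChangeRaster, zones: ZoneMap,
          mode: str = "classified") -> pd.DataFrame:
    """Per-zone influence intensity and decrease/increase partial sums.

    mode="classified" (default) sums CNTL over classified pixels only;
    mode="raw" sums CNTL over every valid pixel of the zone.  In both
    modes ``scntl = sum_decrease + sum_increase`` holds for the classified
    components reported.  Zones without a single classified pixel get
    SCNTL 0 and ``flagged=True``.
    """
    if mode not in ("classified", "raw"):
        raise ValueError(f"unknown scntl mode {mode!r}")
    change.grid.check_compatible(zones.grid)
    c = change.cntl
    rows = []
    for z in zones.zone_ids:
        m = zones.mask(z)
        dec = float(np.nansum(c[m & change.decrease_mask]))
        inc = float(np.nansum(c[m & change.increase_mask]))
        n_classified = int((m & (change.decrease_mask
                                 | change.increase_mask)).sum())
        if mode == "classified":
            total = dec + inc
        else:
            total = float(np.nansum(c[m & change.valid_mask]))
        rows.append((z, total, dec, inc, n_classified, n_classified == 0))
    return pd.DataFrame(rows, columns=["zone_id", "scntl", "sum_decrease",
                                       "sum_increase", "n_classified",
                                       "flagged"])


# ---------------------------------------------------------------------------
# Natural breaks (Fisher–Jenks): exact dynamic programme minimising the
# within-class sum of squared deviations over contiguous classes of the
# sorted values.
# ---------------------------------------------------------------------------

def _class_cost(prefix: np.ndarray, prefix2: np.ndarray,
                i: int, j: int) -> float:
    """SSD of sorted values v[i:j] from their mean (prefix sums)."""
    m = j - i
    s = prefix[j] - prefix[i]
    s2 = prefix2[j] - prefix2[i]
    return s2 - s * s / m


def jenks_breaks(values, k: int = 5, round_to: float | None = None
                 ) -> tuple[float, ...]:
    """Optimal natural-breaks edges (k+1 monotone values).

    Returns ``(min, b1, …, b_{k-1}, max)`` where each interior edge is the
    largest member of its class.  Requires at least k distinct values.
    ``round_to`` optionally rounds every edge to the nearest multiple
    (e.g. 10 000 for display-scale break tables).
    """
    v = np.sort(np.asarray(values, dtype=np.float64))
    n = len(v)
    if len(np.unique(v)) < k:
        raise ValueError(f"need at least {k} distinct values for {k} classes")
    prefix = np.concatenate(([0.0], np.cumsum(v)))
    prefix2 = np.concatenate(([0.0], np.cumsum(v * v)))
    inf = np.inf
    cost = np.full((k + 1, n + 1), inf)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, arg = inf, c - 1
            for i in range(c - 1, j):
                val = cost[c - 1, i] + _class_cost(prefix, prefix2, i, j)
                if val < best - 1e-12:
                    best, arg = val, i
            cost[c, j] = best
            back[c, j] = arg
    cuts = [n]
    j = n
    for c in range(k, 0, -1):
        j = back[c, j]
        cuts.append(j)
    cuts = cuts[::-1]                       # 0 = cuts[0] < … < cuts[k] = n
    edges = [v[0]] + [v[c - 1] for c in cuts[1:]]
    if round_to is not None:
        edges = [round(e / round_to) * round_to for e in edges]
        if any(b <= a for a, b in zip(edges, edges[1:])):
            warnings.warn("rounding collapsed adjacent break edges",
                          stacklevel=2)
    return tuple(float(e) for e in edges)


def jenks_cost(values, edges) -> float:
    """Within-class SSD achieved by the given break edges."""
    v = np.sort(np.asarray(values, dtype=np.float64))
    total = 0.0
    lo = v[0]
    for i, hi in enumerate(edges[1:]):
        if i == 0:
            members = v[(v >= lo) & (v <= hi)]
        else:
            members = v[(v > lo) & (v <= hi)]
        if len(members):
            total += float(((members - members.mean()) ** 2).sum())
        lo = hi
    return total


def classify_level(value: float, breakpoints=PAPER_BREAKS) -> int:
    """Severity level 1 (I, most negative band) … 5 (V, nearest zero).

    Bands are closed on the severe side: a value exactly on an interior
    edge belongs to the more severe (more negative) band.  Values outside
    the edge range are clamped to the nearest band with a warning.
    """
    edges = tuple(breakpoints)
    k = len(edges) - 1
    # edges are class maxima, so a singleton extreme class may duplicate an
    # edge; they must still be non-decreasing overall
    if any(b < a for a, b in zip(edges, edges[1:])) or edges[0] == edges[-1]:
        raise ValueError("breakpoints must be non-decreasing")
    if value < edges[0] or value > edges[-1]:
        warnings.warn(f"value {value} outside break range; clamped",
                      stacklevel=2)
        return 1 if value < edges[0] else k
    for level in range(1, k + 1):
        if value <= edges[level]:
            return level
    return k


# ---------------------------------------------------------------------------
# Anselin Local Moran's I with conditional permutation inference.
# ---------------------------------------------------------------------------

@dataclass
class MoranSettings:
    power: float = 1.0
    row_standardize: bool = True
    alpha: float = 0.05
    n_perm: int = 999
    seed: int | None = None


def _weights(coords: np.ndarray, power: float,
             row_standardize: bool) -> np.ndarray:
    d = np.hypot(coords[:, 0][:, None] - coords[:, 0][None, :],
                 coords[:, 1][:, None] - coords[:, 1][None, :])
    off = ~np.eye(len(coords), dtype=bool)
    if (d[off] == 0).any():
        raise ValueError("coincident zone centroids")
    w = np.zeros_like(d)
    w[off] = 1.0 / d[off] ** power
    if row_standardize:
        w /= w.sum(axis=1, keepdims=True)
    return w


def local_moran(values, coords, power: float = 1.0,
                row_standardize: bool = True, alpha: float = 0.05,
                n_perm: int = 999, seed: int | None = None) -> pd.DataFrame:
    """Local Moran's I per zone with permutation p-values and LISA classes.

    I_i = (x_i − X̄) / S_i² · Σ_{j≠i} w_ij (x_j − X̄),  with
    S_i² = Σ_{j≠i} (x_j − X̄)² / (n − 1) and inverse-distance weights
    (optionally row-standardised).  Significance is assessed by conditional
    permutation: x_i is held fixed while the remaining values are permuted
    among the other zones.  Categories: HH/HL/LH/LL by the signs of
    (x_i − X̄) and of the spatial lag, assigned only when p ≤ alpha, else
    "ns".
    """
    x = np.asarray(values, dtype=np.float64)
    coords = np.asarray(coords, dtype=np.float64)
    n = len(x)
    if n < 3:
        raise ValueError("local Moran's I needs at least 3 zones")
    if np.ptp(x) == 0:
        raise ValueError("constant values: local Moran's I undefined")
    w = _weights(coords, power, row_standardize)
    z = x - x.mean()
    lag = w @ z
    s2 = np.array([(np.delete(z, i) ** 2).sum() for i in range(n)]) / (n - 1)
    local_i = z * lag / s2

    rng = np.random.default_rng(seed)
    p_sim = np.empty(n)
    z_score = np.empty(n)
    for i in range(n):
        pool = np.delete(z, i)
        wi = np.delete(w[i], i)
        perms = np.tile(pool, (n_perm, 1))
        perms = rng.permuted(perms, axis=1)
        sim = z[i] * (perms @ wi) / s2[i]
        larger = int((sim >= local_i[i]).sum())
        if larger > n_perm - larger:
            larger = n_perm - larger
        p_sim[i] = (larger + 1) / (n_perm + 1)
        sd = sim.std()
        z_score[i] = (local_i[i] - sim.mean()) / sd if sd > 0 else np.nan

    cat = np.full(n, "ns", dtype=object)
    sig = p_sim <= alpha
    cat[sig & (z > 0) & (lag > 0)] = "HH"
    cat[sig & (z > 0) & (lag <= 0)] = "HL"
    cat[sig & (z <= 0) & (lag > 0)] = "LH"
    cat[sig & (z <= 0) & (lag <= 0)] = "LL"
    return pd.DataFrame({"local_i": local_i, "p_value": p_sim,
                         "z_score": z_score, "category": cat,
                         "lag": lag})
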