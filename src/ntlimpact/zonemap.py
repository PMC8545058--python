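"""Zone representation: label rasters for cities/provinces/agglomerations.

A :class:`ZoneMap` couples a per-pixel integer label raster (0 = outside any
zone) with a metadata table (name, administrative level, parent zone) and
serves centroids to the spatial-statistics stages.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .rasters import Grid, read_raster, write_raster

__all__ = ["ZoneMap", "rasterize_zones", "aggregate_zones",
           "read_zonemap", "write_zonemap"]

_TABLE_COLUMNS = ["zone_id", "name", "admin_level", "parent_id"]


@dataclass
class ZoneMap:
    """Per-pixel zone labels plus zone metadata.

    ``labels`` is an int array aligned to ``grid`` (0 = no zone).  ``table``
    has one row per zone: zone_id, name, admin_level (city / province /
    agglomeration), parent_id (NaN at the top level).  Centroids are derived
    from member pixel centers and therefore always lie inside the grid.
    """

    labels: np.ndarray
    grid: Grid
    table: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.shape != self.grid.shape:
            raise ValueError("label raster does not match grid shape")
        if (self.labels < 0).any():
            raise ValueError("zone labels must be nonnegative")
        present = np.unique(self.labels)
        present = present[present > 0]
        if self.table is None:
            self.table = pd.DataFrame(
                {"zone_id": present,
                 "name": [f"zone{z}" for z in present],
                 "admin_level": "city",
                 "parent_id": np.nan})
        missing = set(present) - set(self.table["zone_id"])
        if missing:
            raise ValueError(f"labels missing from zone table: {sorted(missing)}")

    @property
    def zone_ids(self) -> np.ndarray:
        return self.table["zone_id"].to_numpy()

    def mask(self, zone_id: int) -> np.ndarray:
        return self.labels == zone_id

    def centroids(self) -> pd.DataFrame:
        """Mean member-pixel-center coordinates (metres) per zone."""
        x, y = self.grid.pixel_centers()
        rows = []
        for z in self.zone_ids:
            rr, cc = np.nonzero(self.labels == z)
            if len(rr) == 0:
                rows.append((z, np.nan, np.nan))
            else:
                rows.append((z, float(x[cc].mean()), float(y[rr].mean())))
        return pd.DataFrame(rows, columns=["zone_id", "x", "y"])


def rasterize_zones(polygons, grid: Grid, table: pd.DataFrame | None = None
                    ) -> ZoneMap:
    """Burn non-overlapping polygons onto the grid by pixel-center membership.

    Parameters
    ----------
    polygons : sequence of (zone_id, shapely geometry)
        Geometries in grid coordinates (metres).  Overlapping pairs are
        rejected with the offending ids listed.
    table : optional zone metadata; synthesized if omitted.
    """
    import shapely

    polygons = list(polygons)
    ids = [int(z) for z, _ in polygons]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate zone ids in polygon set")
    offenders = []
    for i in range(len(polygons)):
        for j in range(i + 1, len(polygons)):
            inter = polygons[i][1].intersection(polygons[j][1])
            if inter.area > 1e-9:
                offenders.append((ids[i], ids[j]))
    if offenders:
        raise ValueError(f"overlapping zone polygons: {offenders}")

    x, y = grid.pixel_centers()
    xx, yy = np.meshgrid(x, y)
    labels = np.zeros(grid.shape, dtype=np.int32)
    for zid, geom in polygons:
        inside = shapely.contains_xy(geom, xx.ravel(), yy.ravel())
        labels.ravel()[inside] = zid
    return ZoneMap(labels, grid, table)


def aggregate_zones(zonemap: ZoneMap, level: str) -> ZoneMap:
    """Merge zones into their parents at the requested administrative level.

    Every labelled zone must declare a parent_id; pixel coverage is
    preserved exactly, so any per-zone sum statistic aggregates additively.
    """
    tab = zonemap.table.set_index("zone_id")
    present = np.unique(zonemap.labels)
    present = present[present > 0]
    parents = tab.loc[present, "parent_id"]
    if parents.isna().any():
        bad = sorted(parents[parents.isna()].index.tolist())
        raise ValueError(f"zones without a parent at level {level!r}: {bad}")
    mapping = parents.astype(int).to_dict()
    labels = np.zeros_like(zonemap.labels)
    for child, parent in mapping.items():
        labels[zonemap.labels == child] = parent
    parent_ids = sorted(set(mapping.values()))
    names = {}
    for pid in parent_ids:
        if pid in tab.index:
            names[pid] = tab.loc[pid, "name"]
        else:
            names[pid] = f"{level}{pid}"
    table = pd.DataFrame({"zone_id": parent_ids,
                          "name": [names[p] for p in parent_ids],
                          "admin_level": level,
                          "parent_id": np.nan})
    return ZoneMap(labels, zonemap.grid, table)


def write_zonemap(path_tif, path_csv, zonemap: ZoneMap) -> None:
    write_raster(path_tif, zonemap.labels, zonemap.grid, kind="zone_labels")
    zonemap.table.to_csv(path_csv, index=False)


def read_zonemap(path_tif, path_csv) -> ZoneMap:
    labels, grid, _ = read_raster(path_tif)
    table = pd.read_csv(path_csv)
    return ZoneMap(labels, grid, table[_TABLE_COLUMNS])
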