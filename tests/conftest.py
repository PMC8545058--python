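import datetime as dt

import numpy as np
import pytest

from ntlimpact import Grid, RasterStack
from ntlimpact.synthetic import (NoiseConfig, SceneConfig, SuppressionProfile,
                                 ZoneSpec, default_scene_config, make_scene)


@pytest.fixture
def small_grid():
    return Grid(40, 40, 500.0)


@pytest.fixture
def quiet_scene(small_grid):
    """A 3-zone scene with no noise and no development increment."""
    window = (dt.date(2020, 1, 23), dt.date(2020, 3, 31))
    zones = tuple(
        ZoneSpec(zone_id=i + 1, center=c, peak=40.0, decay=4.0,
                 suppression=SuppressionProfile(*window, s_min=s,
                                                kind="constant"))
        for i, (c, s) in enumerate(zip([(10, 10), (10, 30), (30, 20)],
                                       [0.5, 0.7, 0.9])))
    return SceneConfig(grid=small_grid, zones=zones,
                       development_increment=0.0, noise=NoiseConfig.none(),
                       seed=3)


@pytest.fixture
def quiet_bundle(quiet_scene):
    return make_scene(quiet_scene)


@pytest.fixture
def default_bundle():
    cfg = default_scene_config(seed=11, grid=Grid(60, 60, 500.0))
    return cfg, make_scene(cfg)


def make_stack(data, start=dt.date(2020, 1, 20), pixel_size=500.0,
               moonlit=None):
    data = np.asarray(data, dtype=float)
    n, rows, cols = data.shape
    dates = tuple(start + dt.timedelta(days=i) for i in range(n))
    return RasterStack(dates, data, Grid(rows, cols, pixel_size),
                       moonlit)
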