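"""End-to-end pipeline: simulate → preprocess → change → intensity →
recovery → trends, driven by one serializable config.

Each stage reads only the config and prior-stage outputs; a run emits every
stage's CSV/TIFF products plus a manifest (config hash, seed, package
versions, per-stage counts) so reruns with the same config and seed are
bit-identical for the deterministic stages.
"""
from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import change as change_mod
from . import intensity as intensity_mod
from . import preprocess as pre_mod
from . import recovery as rec_mod
from . import trends as trends_mod
from .rasters import Grid, RasterStack, read_raster, read_stack, \
    write_raster, write_stack
from .zonemap import ZoneMap, read_zonemap, write_zonemap

log = logging.getLogger("ntlimpact")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, serializable to/from YAML."""

    out_dir: str = "out"
    simulate: bool = True
    seed: int = 0
    n_zones: int = 6
    grid_rows: int = 100
    grid_cols: int = 100
    pixel_size: float = 500.0
    # load-mode inputs (ignored when simulate=True)
    analysis_dir: str | None = None
    baseline_dir: str | None = None
    zones_tif: str | None = None
    zones_csv: str | None = None
    dev_recent_tif: str | None = None
    dev_prior_tif: str | None = None
    mobility_csv: str | None = None
    # stage settings
    threshold_low: float = -1.0
    threshold_high: float = 3.0
    quartile_rule: str = "linear"
    moonless_mode: str = "explicit"       # explicit | ephemeris | all
    breaks_mode: str = "jenks"            # jenks | paper
    breaks_round_to: float | None = None
    scntl_mode: str = "classified"
    moran_power: float = 1.0
    moran_row_standardize: bool = True
    moran_alpha: float = 0.05
    moran_n_perm: int = 999
    lunar_match_mode: str = "offset"      # offset | table
    lunar_offset: int = 12
    rntl_normalize_by_days: bool = True   # matched windows may differ in length
    trend_degree: int = 5
    periods: dict = field(default_factory=dict)   # name → ISO date 4-tuple

    def period(self, name: str) -> rec_mod.PeriodSpec:
        if name in self.periods:
            a, b, c, d = (dt.date.fromisoformat(x) for x in
                          self.periods[name])
            spec = rec_mod.DEFAULT_PERIODS[name]
            return rec_mod.PeriodSpec(name, a, b, c, d, role=spec.role)
        return rec_mod.DEFAULT_PERIODS[name]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
            .encode()).hexdigest()[:16]


def _load_inputs(cfg: PipelineConfig):
    from . import synthetic

    if cfg.simulate:
        grid = Grid(cfg.grid_rows, cfg.grid_cols, cfg.pixel_size)
        scene = synthetic.default_scene_config(seed=cfg.seed,
                                               n_zones=cfg.n_zones,
                                               grid=grid)
        baseline, analysis, zones, truth = synthetic.make_scene(scene)
        dev_recent = truth.unsuppressed
        dev_prior = baseline.data[0]
        mobility = synthetic.make_mobility_series(scene)
        cases = synthetic.make_case_table(scene)
        return baseline, analysis, zones, dev_recent, dev_prior, \
            mobility, cases
    missing = [n for n in ("analysis_dir", "baseline_dir", "zones_tif",
                           "zones_csv", "dev_recent_tif", "dev_prior_tif")
               if getattr(cfg, n) is None]
    if missing:
        raise ValueError(f"simulate=False but inputs missing: {missing}")
    analysis = read_stack(cfg.analysis_dir)
    baseline = read_stack(cfg.baseline_dir)
    zones = read_zonemap(cfg.zones_tif, cfg.zones_csv)
    dev_recent, _, _ = read_raster(cfg.dev_recent_tif)
    dev_prior, _, _ = read_raster(cfg.dev_prior_tif)
    mobility = pd.read_csv(cfg.mobility_csv) if cfg.mobility_csv else None
    return baseline, analysis, zones, dev_recent, dev_prior, mobility, None


def _matched_subset(baseline: RasterStack, stack: RasterStack,
                    cfg: PipelineConfig) -> RasterStack:
    """Baseline layers for exactly the matched dates of the given stack."""
    wanted = {rec_mod.match_lunar_dates(d, mode=cfg.lunar_match_mode,
                                        offset_days=cfg.lunar_offset)
              for d in stack.dates}
    keep = np.array([d in wanted for d in baseline.dates])
    if not keep.any():
        raise ValueError("no baseline dates match the analysis period")
    return baseline.select(keep)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write its products under ``config.out_dir``.

    Returns a result bundle (in-memory tables and the manifest dict).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_digest": config.digest(), "seed": config.seed,
                      "stages": {}}
    import ntlimpact
    manifest["versions"] = {"ntlimpact": ntlimpact.__version__,
                            "numpy": np.__version__,
                            "pandas": pd.__version__}
    results: dict = {"manifest": manifest}

    stage = "simulate" if config.simulate else "load"
    try:
        baseline, analysis, zones, dev_recent, dev_prior, mobility, cases = \
            _load_inputs(config)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    manifest["stages"][stage] = {"n_dates": len(analysis),
                                 "n_zones": int(len(zones.zone_ids))}
    if config.simulate:
        write_stack(out / "analysis", analysis)
        write_stack(out / "baseline", baseline)
        write_zonemap(out / "zones.tif", out / "zones.csv", zones)
        if mobility is not None:
            mobility.to_csv(out / "mobility.csv", index=False)
    if cases is not None:
        valid, quarantined = change_mod.add_existing_infections(cases)
        valid.to_csv(out / "cases.csv", index=False)
        manifest["stages"]["cases"] = {"rows": len(valid),
                                       "quarantined": len(quarantined)}
        results["cases"] = valid

    # -- preprocess ---------------------------------------------------------
    try:
        cleaned, mask = pre_mod.preprocess_stack(
            analysis, moonless_mode=config.moonless_mode)
    except Exception as exc:
        raise RuntimeError(f"stage 'preprocess' failed: {exc}") from exc
    counts = mask.counts(cleaned.dates)
    counts.to_csv(out / "outliers.csv", index=False)
    manifest["stages"]["preprocess"] = {
        "dates_retained": len(cleaned),
        "dates_dropped_moonlit": len(analysis) - len(cleaned),
        "n_high": int(counts["n_high"].sum()),
        "n_low": int(counts["n_low"].sum())}
    results["cleaned"] = cleaned
    log.info("preprocess: %d dates retained, %d high / %d low outliers",
             len(cleaned), counts["n_high"].sum(), counts["n_low"].sum())

    # -- change -------------------------------------------------------------
    try:
        s1 = config.period("S1")
        outbreak = cleaned.select_period(s1.start, s1.end)
        base_s1 = _matched_subset(baseline, outbreak, config)
        dev = change_mod.development_index(dev_recent, dev_prior)
        chg = change_mod.cntl(outbreak.mean_layer(), base_s1.mean_layer(),
                              dev, cleaned.grid,
                              (config.threshold_low, config.threshold_high))
    except Exception as exc:
        raise RuntimeError(f"stage 'change' failed: {exc}") from exc
    write_raster(out / "cntl.tif", chg.cntl.astype(np.float32), chg.grid)
    write_raster(out / "cntl_class.tif", chg.classes, chg.grid)
    areas = change_mod.affected_area(chg, zones)
    areas.to_csv(out / "areas.csv", index=False)
    manifest["stages"]["change"] = {
        "n_decrease": int(chg.decrease_mask.sum()),
        "n_increase": int(chg.increase_mask.sum())}
    results["change"] = chg
    results["areas"] = areas

    # -- intensity ----------------------------------------------------------
    try:
        zi = intensity_mod.scntl(chg, zones, mode=config.scntl_mode)
        if config.breaks_mode == "paper":
            edges = intensity_mod.PAPER_BREAKS
        else:
            edges = intensity_mod.jenks_breaks(
                zi["scntl"], k=5, round_to=config.breaks_round_to)
        zi["level"] = [intensity_mod.classify_level(v, edges)
                       for v in zi["scntl"]]
        cent = zones.centroids().set_index("zone_id")
        coords = cent.loc[zi["zone_id"], ["x", "y"]].to_numpy()
        moran = intensity_mod.local_moran(
            zi["scntl"].to_numpy(), coords, power=config.moran_power,
            row_standardize=config.moran_row_standardize,
            alpha=config.moran_alpha, n_perm=config.moran_n_perm,
            seed=config.seed)
        moran.insert(0, "zone_id", zi["zone_id"].to_numpy())
    except Exception as exc:
        raise RuntimeError(f"stage 'intensity' failed: {exc}") from exc
    zi.to_csv(out / "intensity.csv", index=False)
    moran.to_csv(out / "moran.csv", index=False)
    manifest["stages"]["intensity"] = {
        "breaks": list(edges),
        "zones_flagged": int(zi["flagged"].sum())}
    results["intensity"] = zi
    results["moran"] = moran

    # -- recovery -----------------------------------------------------------
    try:
        rec_tables = {}
        for name in ("feb", "mar"):
            spec = config.period(name)
            sub = cleaned.select_period(spec.start, spec.end)
            base_sub = _matched_subset(baseline, sub, config)
            rec_tables[name] = rec_mod.rntl(
                sub, base_sub, zones,
                normalize_by_days=config.rntl_normalize_by_days)
        dvals = rec_mod.d_value(rec_tables["mar"], rec_tables["feb"])
        recovery = rec_tables["feb"].rename(columns={"rntl": "rntl_feb"})[
            ["zone_id", "rntl_feb"]].merge(
            rec_tables["mar"].rename(columns={"rntl": "rntl_mar"})[
                ["zone_id", "rntl_mar"]], on="zone_id").merge(
            dvals, on="zone_id")
        if mobility is not None:
            m_feb = rec_mod.period_iict_recovery(
                mobility, config.period("feb"),
                match_mode=config.lunar_match_mode,
                offset_days=config.lunar_offset)
            recovery = recovery.merge(
                m_feb.rename(columns={"m": "m_feb"})[["zone_id", "m_feb"]],
                on="zone_id", how="left")
            crosstab, excluded = rec_mod.recovery_crosstab(
                rec_tables["feb"], m_feb)
            crosstab.to_csv(out / "recovery_crosstab.csv")
            manifest["stages"].setdefault("recovery", {})["excluded_zones"] \
                = [int(z) for z in excluded]
    except Exception as exc:
        raise RuntimeError(f"stage 'recovery' failed: {exc}") from exc
    recovery.to_csv(out / "recovery.csv", index=False)
    manifest["stages"].setdefault("recovery", {})["n_zones"] = len(recovery)
    results["recovery"] = recovery

    # -- trends -------------------------------------------------------------
    try:
        base_full = _matched_subset(baseline, cleaned, config)
        series = trends_mod.daily_difference_series(
            cleaned, base_full.mean_layer(), zones,
            chg.decrease_mask, chg.increase_mask)
        trends = trends_mod.zone_trends(series, degree=config.trend_degree)
    except Exception as exc:
        raise RuntimeError(f"stage 'trends' failed: {exc}") from exc
    series.to_csv(out / "daily_series.csv", index=False)
    trends.drop(columns=["d_coef", "i_coef"]).to_csv(
        out / "trends.csv", index=False)
    manifest["stages"]["trends"] = {
        "n_m_type": int((trends["traj_type"] == "M").sum()),
        "n_inverted_u": int((trends["traj_type"] == "inverted_U").sum())}
    results["trends"] = trends

    config.to_yaml(out / "config.yaml")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return results
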