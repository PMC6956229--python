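"""End-to-end pipeline: library -> descriptors -> profiles -> fits ->
classification -> PLS -> design space.

Every stage is a thin call into the corresponding module; this file owns
only sequencing, configuration, file I/O and the run log. All thresholds
are config-surfaced with the study defaults and logged for audit.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design_space as ds
from . import metrology, models, pls, rcbcs, synthetic

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("rollcompact")


@dataclass
class PipelineConfig:
    """All tunable knobs of the pipeline with the study defaults."""

    descriptor_table: str | None = None   # input CSVs; None -> synthesize
    ribbon_table: str | None = None
    out_dir: str = "results"
    n_materials: int = 81
    pressures: tuple = metrology.PRESSURE_GRID
    sf_min: float = 0.6
    sf_max: float = 0.8
    ts_min: float = 1.0            # MPa
    r2_threshold: float = 0.7      # fit applicability screen
    cv_folds: int = 7
    a_max: int = 10
    q2_gain: float = 0.01          # component-selection stopping gain
    vip_cutoff: float = 1.0
    confidence_level: float = 0.95
    sigma_ts: float = 0.05
    sigma_sf: float = 0.01
    replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.sf_min < self.sf_max <= 1):
            raise ValueError("require 0 < sf_min < sf_max <= 1")
        if self.ts_min <= 0:
            raise ValueError("ts_min must be positive")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "pressures" in raw:
        raw["pressures"] = tuple(raw["pressures"])
    return PipelineConfig(**raw)


def _setup_log(out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for h in log.handlers:
        h.close()
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s",
                                           datefmt="%Y-%m-%dT%H:%M:%S"))
    log.handlers = [handler]
    log.setLevel(logging.INFO)


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {err}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns a dict of the in-memory artifacts (tables, models, maps).
    Deterministic under a fixed seed: two runs produce byte-identical
    output tables.
    """
    out = Path(config.out_dir)
    _setup_log(out)
    import rollcompact
    log.info("rollcompact %s | seed=%d | config=%s",
             getattr(rollcompact, "__version__", "dev"), config.seed,
             json.dumps(dataclasses.asdict(config), default=str))

    bundle: dict = {}
    stage = "inputs"
    try:
        if config.descriptor_table and config.ribbon_table:
            descriptors = pd.read_csv(config.descriptor_table)
            samples = metrology.read_ribbon_table(config.ribbon_table)
            truth = None
        else:
            syn = synthetic.SyntheticConfig.with_n(
                config.n_materials, pressures=config.pressures,
                sigma_ts=config.sigma_ts, sigma_sf=config.sigma_sf,
                replicates=config.replicates, seed=config.seed)
            descriptors, ribbons, truth = synthetic.generate_library(syn)
            ribbons.to_csv(out / "ribbon_measurements.csv", index=False,
                           float_format="%.6g")
            truth.to_csv(out / "ground_truth.csv", index=False, float_format="%.6g")
            samples = metrology.read_ribbon_table(out / "ribbon_measurements.csv")
        descriptors.to_csv(out / "descriptors.csv", index=False, float_format="%.6g")
        bundle["descriptors"], bundle["truth"] = descriptors, truth
        log.info("inputs: %d materials, %d ribbon rows", len(descriptors), len(samples))

        stage = "profiles"
        profiles = metrology.profiles_from_table(samples)
        prof_table = metrology.profile_table(profiles)
        prof_table.to_csv(out / "profiles.csv", index=False, float_format="%.6g")
        freq = metrology.splitting_frequency_table(samples)
        freq.to_csv(out / "splitting_frequency.csv", float_format="%.6g")
        bundle["profiles"], bundle["profile_table"], bundle["splitting"] = \
            profiles, prof_table, freq

        stage = "fits"
        fit_tab = models.fit_table(profiles)
        fit_tab.to_csv(out / "compaction_fits.csv", index=False, float_format="%.6g")
        fit_tab.to_json(out / "compaction_fits.json", orient="records", indent=1)
        bundle["fits"] = fit_tab
        log.info("fits: %d/%d R-D applicable, %d/%d power applicable",
                 int(fit_tab.rd_applicable.sum()), len(fit_tab),
                 int(fit_tab.pow_applicable.sum()), len(fit_tab))

        stage = "classification"
        labels = rcbcs.classify_all(profiles, sf_min=config.sf_min,
                                    sf_max=config.sf_max, ts_min=config.ts_min)
        lab_tab = rcbcs.label_table(labels)
        lab_tab.to_csv(out / "rcbcs_labels.csv", index=False)
        types = dict(zip(descriptors["material_id"], descriptors.get(
            "type", pd.Series("excipient", index=descriptors.index))))
        by_mat: dict[str, list] = {}
        for s in samples:
            by_mat.setdefault(s.material_id, []).append(s)
        summary = rcbcs.category_summary(labels, types, by_mat)
        summary.to_csv(out / "category_summary.csv", float_format="%.6g")
        rcbcs.ts_sf_map(profiles, config.sf_min, config.sf_max, config.ts_min).to_csv(
            out / "ts_sf_map.csv", index=False, float_format="%.6g")
        bundle["labels"], bundle["category_summary"] = labels, summary
        log.info("classification: %s", lab_tab["category"].value_counts().to_dict())

        stage = "pls"
        X, Y, meta = pls.assemble_lvm_dataset(
            descriptors.drop(columns=["type"], errors="ignore"), prof_table, fit_tab)
        a_max = min(config.a_max, X.shape[1], X.shape[0] - 1)
        q2_curve, rmsecv = pls.cross_validate(X, Y, a_max, n_folds=config.cv_folds,
                                              seed=config.seed)
        a = pls.select_components(q2_curve, config.q2_gain, config.a_max)
        model = pls.fit_pls(X, Y, a)
        model.q2y_curve = q2_curve[:a]
        model.q2y_cum = float(q2_curve[a - 1])
        _, model.rmsecv = pls.cross_validate(X, Y, a, n_folds=config.cv_folds,
                                             seed=config.seed)
        model.save(out / "pls_model.json")
        vip_tab = pd.DataFrame({"variable": model.x_columns, "VIP": pls.vip(model)}
                               ).sort_values("VIP", ascending=False)
        vip_tab.to_csv(out / "vip.csv", index=False, float_format="%.6g")
        pls.coefficients(model).to_csv(out / "coefficients.csv", index=False,
                                       float_format="%.6g")
        diag = pd.DataFrame([{
            "model": "full", "LVs": a, "R2Xcum": model.r2x_cum,
            "R2Ycum": model.r2y_cum, "Q2Ycum": model.q2y_cum,
            "RMSECV_TS": model.rmsecv[0], "RMSECV_SF": model.rmsecv[1],
        }])
        bundle.update(X=X, Y=Y, meta=meta, model=model, vip=vip_tab)
        log.info("pls: n=%d, A=%d, R2Y=%.3f Q2Y=%.3f", len(X), a,
                 model.r2y_cum, model.q2y_cum)

        stage = "design_space"
        refined, kept = ds.refine_model(model, X, Y, vip_cutoff=config.vip_cutoff,
                                        n_folds=config.cv_folds, seed=config.seed)
        refined.save(out / "pls_model_refined.json")
        diag = pd.concat([diag, pd.DataFrame([{
            "model": "refined", "LVs": refined.n_components,
            "R2Xcum": refined.r2x_cum, "R2Ycum": refined.r2y_cum,
            "Q2Ycum": refined.q2y_cum,
            "RMSECV_TS": refined.rmsecv[0], "RMSECV_SF": refined.rmsecv[1],
        }])], ignore_index=True)
        diag.to_csv(out / "pls_diagnostics.csv", index=False, float_format="%.6g")
        dsmap = ds.map_targets(refined, ts_min=config.ts_min,
                               sf_band=(config.sf_min, config.sf_max),
                               level=config.confidence_level)
        np.savetxt(out / "design_space_mask.csv", dsmap.region.astype(int),
                   fmt="%d", delimiter=",")
        with open(out / "design_space_region.json", "w") as fh:
            json.dump({"radius": dsmap.radius, "area_fraction": dsmap.area_fraction,
                       "boundary": dsmap.boundary}, fh, indent=1)
        membership = ds.project_material(refined, X, dsmap, ts_min=config.ts_min,
                                         sf_band=(config.sf_min, config.sf_max))
        membership = pd.concat([meta.reset_index(drop=True),
                                membership.reset_index(drop=True)], axis=1)
        membership.to_csv(out / "design_space_membership.csv", index=False,
                          float_format="%.6g")
        bundle.update(refined=refined, kept_variables=kept, dsmap=dsmap,
                      membership=membership, diagnostics=diag)
        log.info("design space: kept=%s, radius=%.3f, area fraction=%.3f",
                 kept, dsmap.radius, dsmap.area_fraction)
        log.info("pipeline complete; outputs in %s", out)
    except Exception as err:  # annotate with the failing stage
        if isinstance(err, StageError):
            raise
        log.exception("stage %s failed", stage)
        raise StageError(stage, err) from err
    finally:
        for h in log.handlers:
            h.close()
        log.handlers = []

    return bundle
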