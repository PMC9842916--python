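"""End-to-end study replica: simulate -> CST impairment -> cluster GLM ->
ROI inference -> VLSM -> longitudinal LMM, driven by one YAML config."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import clustermap, lmm, stats, vlsm
from .cst import impairment_profile
from .grid import GridSpec
from .synthetic import Cohort, CohortConfig, simulate_cohort, write_cohort

logger = logging.getLogger(__name__)

STAGES = ("simulate", "cst", "cluster_glm", "roi_stats", "vlsm", "lmm")


@dataclass
class Thresholds:
    inclusion_fraction: float = 0.10
    min_cluster: int = 10
    voxel_p: float = 0.01
    cluster_p: float = 0.05
    q: float = 0.05
    n_sims: int = 1000
    fwhm_mm: float = 10.0

    def validate(self) -> None:
        for name in ("inclusion_fraction", "voxel_p", "cluster_p", "q"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.min_cluster < 0:
            raise ValueError("min_cluster must be >= 0")
        if self.n_sims < 100:
            raise ValueError("n_sims must be >= 100")
        if self.fwhm_mm <= 0:
            raise ValueError("fwhm_mm must be > 0")


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    seeds: dict[str, int] = field(
        default_factory=lambda: {"simulate": 1, "replication": 2, "monte_carlo": 3}
    )
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: float = 2.0

    def validate(self) -> None:
        self.thresholds.validate()
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for key in ("simulate", "replication"):
            if key not in self.seeds:
                raise ValueError(f"missing seed {key!r}")
        if self.stages.get("cluster_glm", False) and "monte_carlo" not in self.seeds:
            raise ValueError("cluster_glm stage enabled but no monte_carlo seed given")


_KNOWN_KEYS = {"cohort", "thresholds", "stages", "seeds", "grid_shape", "voxel_size_mm"}


def validate_config(path: str | Path) -> RunConfig:
    """Load a YAML run config; unknown keys and out-of-range values rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cohort_kwargs = raw.get("cohort", {})
    known_cohort = set(CohortConfig.__dataclass_fields__)
    bad = set(cohort_kwargs) - known_cohort
    if bad:
        raise ValueError(f"unknown cohort keys: {sorted(bad)}")
    thr_kwargs = raw.get("thresholds", {})
    bad = set(thr_kwargs) - set(Thresholds.__dataclass_fields__)
    if bad:
        raise ValueError(f"unknown threshold keys: {sorted(bad)}")
    cfg = RunConfig(
        cohort=CohortConfig(**cohort_kwargs),
        thresholds=Thresholds(**thr_kwargs),
        stages={**{s: True for s in STAGES}, **raw.get("stages", {})},
        seeds={**{"simulate": 1, "replication": 2, "monte_carlo": 3}, **raw.get("seeds", {})},
        grid_shape=tuple(raw.get("grid_shape", (32, 32, 32))),
        voxel_size_mm=float(raw.get("voxel_size_mm", 2.0)),
    )
    cfg.validate()
    return cfg


@dataclass
class PipelineResult:
    out_dir: Path
    discovery: Cohort
    replication: Cohort | None
    rois: dict[str, clustermap.RoiSet] = field(default_factory=dict)
    ancova: pd.DataFrame | None = None
    wefm_corr: pd.DataFrame | None = None
    cst_corr: pd.DataFrame | None = None
    vlsm_results: list[vlsm.VlsmResult] = field(default_factory=list)
    lmm_fits: list[lmm.LmmFit] = field(default_factory=list)
    lmm_report: pd.DataFrame | None = None
    manifest: dict[str, Any] = field(default_factory=dict)


def _patient_hc_design(cohort: Cohort, measure: str) -> tuple[list, pd.DataFrame]:
    """Sheets + design (patients vs HC) for one measure."""
    subj = cohort.subject_frame
    sheets = [cohort.sheets[(sid, measure)] for sid in subj["subject_id"]]
    design = pd.DataFrame(
        {
            "group": (subj["group"] != "HC").astype(int).to_numpy(),
            "age": subj["age"].to_numpy(),
            "sex": subj["sex"].to_numpy(),
            "scanner": subj["scanner"].to_numpy(),
            "global": [s.global_value for s in sheets],
        }
    )
    return sheets, design


def run_pipeline(config: RunConfig, out_dir: str | Path) -> PipelineResult:
    """Run the enabled stages in dependency order, writing per-stage outputs
    and a manifest; reruns with the same config are bit-identical."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"stages": {}, "seeds": dict(config.seeds)}
    grid = GridSpec(shape=config.grid_shape, voxel_size=(config.voxel_size_mm,) * 3)

    def _stage(name):
        t0 = time.perf_counter()

        def done(**extra):
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3),
                **extra,
            }
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)

        return done

    # -- simulate ----------------------------------------------------------
    done = _stage("simulate")
    cohort_cfg = CohortConfig(**{**asdict_cohort(config.cohort), "seed": config.seeds["simulate"]})
    discovery = simulate_cohort(cohort_cfg, grid)
    rep_cfg = CohortConfig(**{**asdict_cohort(config.cohort), "seed": config.seeds["replication"]})
    replication = simulate_cohort(rep_cfg, grid, discovery.atlas)
    if config.stages.get("simulate", True):
        write_cohort(discovery, out / "simulate" / "discovery")
        write_cohort(replication, out / "simulate" / "replication")
    done(n_patients=cohort_cfg.n_patients, n_controls=cohort_cfg.n_controls)

    result = PipelineResult(out_dir=out, discovery=discovery, replication=replication)
    thr = config.thresholds
    chronic = discovery.chronic_table()
    patients = discovery.subject_frame.query("group != 'HC'")

    # -- CST impairment ----------------------------------------------------
    if config.stages.get("cst", True):
        done = _stage("cst")
        rows = []
        for sid in patients["subject_id"]:
            hemi = discovery.truth.hemispheres[sid]
            prof = impairment_profile(discovery.lesions[sid], discovery.atlas, hemi)
            for subset, pct in prof.percentages.items():
                rows.append(
                    {"subject_id": sid, "subset": subset, "percentage": pct,
                     "argmax_slice": prof.argmax_slice[subset]}
                )
        (out / "cst").mkdir(exist_ok=True)
        pd.DataFrame(rows).to_csv(out / "cst" / "impairment.tsv", sep="\t", index=False)
        done(n_profiles=len(patients))

    # -- cluster GLM + ROI confirmation ------------------------------------
    if config.stages.get("cluster_glm", True):
        done = _stage("cluster_glm")
        (out / "cluster_glm").mkdir(exist_ok=True)
        measures = sorted(set(discovery.config.roi_measures.values()))
        n_rois = 0
        for measure in measures:
            sheets, design = _patient_hc_design(discovery, measure)
            stat = clustermap.fit_pointwise_glm(sheets, design)
            stat = clustermap.monte_carlo_cluster_correct(
                stat,
                n_sims=thr.n_sims,
                voxel_p=thr.voxel_p,
                cluster_p=thr.cluster_p,
                fwhm_mm=thr.fwhm_mm,
                spacing_mm=config.voxel_size_mm,
                seed=config.seeds["monte_carlo"],
            )
            rep_sheets, rep_design = _patient_hc_design(replication, measure)
            rois = clustermap.replicate_rois(stat, rep_sheets, rep_design, alpha=0.05)
            for r in rois.rois:
                r.name = f"{measure}_{r.name}"
            result.rois[measure] = rois
            n_rois += len(rois.rois)
            clustermap.cluster_table(stat, config.voxel_size_mm).to_csv(
                out / "cluster_glm" / f"clusters_{measure}.tsv", sep="\t", index=False
            )
        done(n_confirmed_rois=n_rois)

    # -- ROI inference -----------------------------------------------------
    if config.stages.get("roi_stats", True):
        done = _stage("roi_stats")
        (out / "roi_stats").mkdir(exist_ok=True)
        result.ancova = stats.roi_ancova_table(chronic)
        result.wefm_corr = stats.wefm_partial_correlations(chronic, q=thr.q)
        result.cst_corr = stats.cst_correlations(chronic, q=thr.q)
        result.ancova.to_csv(out / "roi_stats" / "ancova.tsv", sep="\t", index=False)
        result.wefm_corr.to_csv(out / "roi_stats" / "wefm_corr.tsv", sep="\t", index=False)
        result.cst_corr.to_csv(out / "roi_stats" / "cst_corr.tsv", sep="\t", index=False)
        done(n_ancova=len(result.ancova))

    # -- VLSM ---------------------------------------------------------------
    if config.stages.get("vlsm", True):
        done = _stage("vlsm")
        (out / "vlsm").mkdir(exist_ok=True)
        left_ids = [
            sid for sid in patients["subject_id"]
            if discovery.truth.hemispheres[sid] == "left"
        ]
        masks = [discovery.lesions[sid] for sid in left_ids]
        rois = sorted(discovery.config.roi_measures.items())
        chronic_left = chronic[chronic["subject_id"].isin(left_ids)]
        result.vlsm_results = vlsm.vlsm_batch(
            masks, chronic_left, rois,
            min_incidence=thr.inclusion_fraction,
            min_cluster=thr.min_cluster,
            q=thr.q,
        )
        vlsm.vlsm_cluster_table(result.vlsm_results).to_csv(
            out / "vlsm" / "clusters.tsv", sep="\t", index=False
        )
        done(n_maps=len(result.vlsm_results))

    # -- longitudinal LMM ---------------------------------------------------
    if config.stages.get("lmm", True):
        done = _stage("lmm")
        (out / "lmm").mkdir(exist_ok=True)
        fits = []
        for (roi, measure), sub in discovery.table.groupby(["roi", "measure"], sort=True):
            fits.append(lmm.fit_all_groups(sub, roi=roi, measure=measure))
        fits = lmm.correct_slope_family(fits, q=thr.q)
        result.lmm_fits = fits
        result.lmm_report = lmm.lmm_table(fits, q=thr.q)
        result.lmm_report.to_csv(out / "lmm" / "trajectories.tsv", sep="\t", index=False)
        done(n_rois=len(fits))

    result.manifest = manifest
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return result


def asdict_cohort(cfg: CohortConfig) -> dict:
    """CohortConfig -> kwargs dict preserving Effect objects."""
    d = asdict(cfg)
    d["effect_table"] = cfg.effect_table
    return d
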