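"""End-to-end orchestration: phantom -> habitats -> radiomics -> selection
-> evaluation, with per-stage artifacts, a checksummed manifest and a
human-readable summary.

Each stage reads only the files the previous stage wrote into the run
directory, so the lineage recorded in the manifest is real.  Reruns with the
same configuration produce bit-identical artifact checksums (NIfTI gzip
members are written with a zeroed timestamp).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import phantom as ph
from .config import RunConfig
from .evaluation import EvalConfig, repeated_trials
from .habitats import ROI_NAMES, dice, segment_subject
from .learners import rf_rfe
from .radiomics import (FeatureTable, RadiomicsConfig, assemble_feature_table,
                        extract_subject_features, roi_volumes)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {detail}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def build_phantom_spec(cfg: RunConfig) -> ph.PhantomSpec:
    spec = ph.PhantomSpec(grid_shape=tuple(cfg.phantom.grid_shape),
                          voxel_size=tuple(cfg.phantom.voxel_size),
                          n_short=cfg.phantom.n_short,
                          n_long=cfg.phantom.n_long,
                          seed=cfg.seed)
    scale = cfg.phantom.noise_sd
    if scale != 1.0:
        for gm in spec.group_models.values():
            gm.noise_sd = {k: v * scale for k, v in gm.noise_sd.items()}
    return spec


def _stage_seeds(seed: int) -> Dict[str, int]:
    vals = np.random.default_rng(seed).integers(0, 2 ** 31 - 1, size=4)
    return {"segmentation": int(vals[0]), "selection": int(vals[1]),
            "evaluation": int(vals[2]), "extra": int(vals[3])}


def run_pipeline(cfg: RunConfig, out_dir: Optional[Path] = None) -> Path:
    """Execute every stage and return the run directory."""
    run_dir = Path(out_dir if out_dir is not None else cfg.out)
    run_dir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    artifacts: List[Path] = []
    timings: Dict[str, float] = {}
    failed_marker = run_dir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    def record(path: Path) -> None:
        artifacts.append(path)

    try:
        # ---------------- stage 1: phantom cohort ----------------
        t0 = time.perf_counter()
        stage = "phantom"
        spec = build_phantom_spec(cfg)
        phantom_dir = run_dir / "phantom"
        manifest = ph.write_cohort(phantom_dir, spec)
        record(phantom_dir / "manifest.csv")
        timings[stage] = time.perf_counter() - t0
        logger.info("phantom stage: %d subjects in %.1fs",
                    len(manifest), timings[stage])

        # ---------------- stage 2: habitat segmentation ----------------
        t0 = time.perf_counter()
        stage = "habitats"
        hab_dir = run_dir / "habitats"
        hab_dir.mkdir(exist_ok=True)
        seg_seeds = np.random.default_rng(seeds["segmentation"]).integers(
            0, 2 ** 31 - 1, size=len(manifest))
        catalogs = {}
        dice_summary = {}
        subjects_loaded = {}
        for i, sid in enumerate(manifest["subject_id"]):
            volumes, truth = ph.read_subject(phantom_dir / sid)
            subjects_loaded[sid] = (volumes, truth)
            catalog = segment_subject(
                volumes, seed=int(seg_seeds[i]),
                n_init=cfg.segmentation.n_init,
                slicewise=cfg.segmentation.slicewise)
            catalogs[sid] = catalog
            sdir = hab_dir / sid
            sdir.mkdir(exist_ok=True)
            counts = {}
            for name in ROI_NAMES:
                ph.save_nifti(sdir / f"roi_{name}.nii.gz",
                              catalog.masks[name], volumes.voxel_size)
                record(sdir / f"roi_{name}.nii.gz")
                counts[name] = int(catalog.masks[name].sum())
            entry = {"voxel_counts": counts}
            if truth is not None:
                entry["dice_vs_truth"] = {
                    "necrotic": dice(catalog.masks["necrotic"],
                                     truth.compartment_labels == 1),
                    "CE": dice(catalog.masks["CE"],
                               truth.compartment_labels == 3),
                    "LMD": dice(catalog.masks["LMD"], truth.md_low_mask),
                    "LrCBV": dice(catalog.masks["LrCBV"],
                                  truth.cbv_low_mask),
                }
            dice_summary[sid] = entry
        (hab_dir / "segmentation_summary.json").write_text(
            json.dumps(dice_summary, indent=2, sort_keys=True))
        record(hab_dir / "segmentation_summary.json")
        timings[stage] = time.perf_counter() - t0

        # ---------------- stage 3: radiomics ----------------
        t0 = time.perf_counter()
        stage = "radiomics"
        rad_dir = run_dir / "radiomics"
        rad_dir.mkdir(exist_ok=True)
        rcfg = RadiomicsConfig(n_levels=cfg.radiomics.n_levels)
        vectors = []
        vol_rows = []
        for sid in manifest["subject_id"]:
            volumes, _ = subjects_loaded[sid]
            vectors.append(extract_subject_features(volumes, catalogs[sid],
                                                    rcfg))
            vr = roi_volumes(catalogs[sid], volumes.tumor_mask,
                             volumes.voxel_size)
            row = {"subject_id": sid}
            row.update({f"{roi}_cm3": vr.loc[roi, "absolute_cm3"]
                        for roi in vr.index})
            vol_rows.append(row)
        table = assemble_feature_table(
            vectors, list(manifest["survival_class"]),
            subject_ids=list(manifest["subject_id"]),
            provenance={"seed": cfg.seed})
        table.to_csv(rad_dir / "features.csv")
        record(rad_dir / "features.csv")
        volumes_df = pd.DataFrame(vol_rows).set_index("subject_id")
        volumes_df.insert(0, "group", manifest.set_index("subject_id")["group"])
        volumes_df.to_csv(rad_dir / "volumes.csv", float_format="%.6f")
        record(rad_dir / "volumes.csv")
        group_means = volumes_df.groupby("group").mean().round(4)
        timings[stage] = time.perf_counter() - t0

        # ---------------- stage 4: feature selection ----------------
        t0 = time.perf_counter()
        stage = "selection"
        sel_dir = run_dir / "selection"
        sel_dir.mkdir(exist_ok=True)
        n_selected = None
        if cfg.selection.enabled:
            selection = rf_rfe(table.features, table.y01(),
                               n_select=cfg.selection.n_select,
                               step_fraction=cfg.selection.step_fraction,
                               n_trees=cfg.selection.n_trees,
                               seed=seeds["selection"])
            selection.to_json(sel_dir / "selection.json")
            record(sel_dir / "selection.json")
            n_selected = len(selection.selected)
        else:
            logger.info("selection stage skipped (--no-rfe)")
        timings[stage] = time.perf_counter() - t0

        # ---------------- stage 5: evaluation ----------------
        t0 = time.perf_counter()
        stage = "evaluation"
        eval_dir = run_dir / "evaluation"
        eval_dir.mkdir(exist_ok=True)
        table_disk = FeatureTable.from_csv(rad_dir / "features.csv")
        ecfg = EvalConfig(use_rfe=cfg.selection.enabled,
                          n_select=cfg.selection.n_select,
                          rfe_step_fraction=cfg.selection.step_fraction,
                          rfe_trees=cfg.selection.n_trees,
                          n_estimators=cfg.evaluation.n_estimators,
                          learning_rate=cfg.evaluation.learning_rate,
                          max_depth=cfg.evaluation.max_depth,
                          subsample=cfg.evaluation.subsample,
                          tune=cfg.evaluation.tune,
                          paper_faithful=cfg.evaluation.paper_faithful,
                          threshold=cfg.evaluation.threshold)
        report = repeated_trials(table_disk, ecfg,
                                 n_trials=cfg.evaluation.trials,
                                 base_seed=seeds["evaluation"])
        report.to_json(eval_dir / "cv_report.json")
        report.save_roc_csv(eval_dir / "roc.csv")
        report.save_accuracy_csv(eval_dir / "trial_accuracies.csv")
        for f in ("cv_report.json", "roc.csv", "trial_accuracies.csv"):
            record(eval_dir / f)
        try:
            report.plot_roc(eval_dir / "roc.png")
            report.plot_trial_accuracies(eval_dir / "trial_accuracies.png")
        except Exception as err:  # plotting is best-effort
            logger.warning("plotting failed: %s", err)
        timings[stage] = time.perf_counter() - t0

        # ---------------- manifest + summary ----------------
        summary = {
            "config": cfg.model_dump(),
            "n_subjects": int(len(manifest)),
            "n_features": int(table.n_features),
            "n_selected": n_selected,
            "mean_metrics": report.mean_metrics,
            "sd_metrics": report.sd_metrics,
            "volume_group_means_cm3": group_means.to_dict(),
        }
        logger.info("stage timings (s): %s",
                    {k: round(v, 2) for k, v in timings.items()})
        (run_dir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True, default=str))
        lineage = {
            str(p.relative_to(run_dir)): _sha256(p)
            for p in sorted(artifacts)
        }
        (run_dir / "run_manifest.json").write_text(
            json.dumps({"seed": cfg.seed, "artifacts": lineage},
                       indent=2, sort_keys=True))
        return run_dir
    except Exception as err:
        failed_marker.write_text(f"stage={stage}\nerror={err}\n")
        if isinstance(err, PipelineError):
            raise
        raise PipelineError(stage, str(err)) from err
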