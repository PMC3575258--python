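"""End-to-end orchestration on simulated datasets.

Stage order mirrors the analysis chain: features -> detection -> map ->
artifact replacement -> segmentation -> coordinate normalisation ->
feature extraction -> statistics.  Every stage is logged with parameters
and timing; failures abort with the stage name.
"""

from __future__ import annotations

import json
import logging
import time
from contextlib import contextmanager
from pathlib import Path

import numpy as np
import pandas as pd

from .detection import classify_channels
from .features import channel_features
from .geometry import bipolar_rms, project_map, projection_median, region_mean_intensity
from .io import PipelineConfig, write_map, write_qc_report
from .mapping import InterpolationInfeasibleError, compute_map, replace_artifact_values
from .segmentation import segment_map
from .stats import friedman_blocked, friedman_repeated, lda_loo, normalize_per_muscle
from .synthetic import ConditionRecord, TaskModel, iter_task_dataset

__all__ = ["PipelineError", "run_pipeline", "extract_condition_features", "dataset_statistics"]

log = logging.getLogger("hdemgmap")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@contextmanager
def _stage(name: str):
    t0 = time.perf_counter()
    log.info("stage %s: start", name)
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(name, exc) from exc
    log.info("stage %s: done in %.2f s", name, time.perf_counter() - t0)


def _segment_with_fallback(amap, config: PipelineConfig, seed):
    """Segment a map, deepening the dome when the opening removes all
    support (weak antagonist maps), and falling back to the top-quartile
    region for genuinely flat maps."""
    from dataclasses import replace

    from .segmentation import NoRegionError, SegmentationConfig, SegmentedMap

    candidates = [config.segmentation]
    if config.segmentation.h_mode == "fraction":
        for frac in (0.5, 0.9):
            if frac > config.segmentation.h:
                candidates.append(replace(config.segmentation, h=frac))
    for cfg in candidates:
        try:
            return segment_map(amap, cfg, seed=seed)
        except NoRegionError:
            continue
    log.warning("no dome region survives the opening; using top-quartile region")
    q = np.quantile(amap.intensity, 0.75)
    labels = (amap.intensity >= q).astype(int)
    dome = np.where(labels > 0, amap.intensity - q, 0.0)
    return SegmentedMap(dome=dome, labels=labels, selected=1, region_table=[],
                        source=amap)


def extract_condition_features(record: ConditionRecord, config: PipelineConfig) -> list[dict]:
    """QC, map, segment and parameterise every muscle array of one trial."""
    rows = []
    for muscle, rec in record.recordings.items():
        feats = channel_features(rec, config.epoching, mains_hz=config.mains_hz)
        mask = classify_channels(feats, config.detector)
        amap = compute_map(rec, 0, config.epoching, config.filter)
        try:
            amap = replace_artifact_values(amap, mask)
        except InterpolationInfeasibleError:
            log.warning("replacement infeasible for %s (subject %d, %s %d%%): using raw map",
                        muscle, record.subject, record.task, record.effort_pct)
        seed = (rec.grid.origin_row, rec.grid.origin_col)
        seg = _segment_with_fallback(amap, config, seed)
        mu_x = projection_median(project_map(seg, "x"))
        mu_y = projection_median(project_map(seg, "y"))
        origin = (rec.grid.origin_row, rec.grid.origin_col)
        distal = (min(rec.grid.origin_row + 1, rec.grid.n_rows - 1), rec.grid.origin_col)
        rows.append({
            "subject": record.subject,
            "task": record.task,
            "effort": record.effort_pct,
            "muscle": muscle,
            "rms_av_hd": region_mean_intensity(amap, seg),
            "rms_av_bip": bipolar_rms(rec, origin, distal, 0, config.epoching, config.filter),
            "mu_x": mu_x,
            "mu_y": mu_y,
            "n_flagged": mask.n_flagged,
        })
    return rows


def dataset_statistics(table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Statistical battery over the per-condition feature table."""
    out: dict = {}
    norm = normalize_per_muscle(table)
    muscles = sorted(table["muscle"].unique())

    # electrode-type comparison: two-way Friedman, blocks = muscle,
    # replicated cells = all (subject, task, effort) observations
    piv = norm.sort_values(["muscle", "subject", "task", "effort"])
    reps = len(piv) // len(muscles)
    data = np.column_stack([piv["rms_av_hd"].to_numpy(), piv["rms_av_bip"].to_numpy()])
    res = friedman_blocked(data, replication=reps, alpha=alpha)
    out["friedman_electrode_type"] = {
        "chi2": res.chi2, "dof": res.dof, "p": res.p, "significant": bool(res.significant)
    }

    # spatial-distribution changes: repeated-measures Friedman over the
    # task x effort conditions per muscle, Bonferroni corrected
    for var in ("mu_x", "mu_y"):
        per_muscle = {}
        for muscle in muscles:
            sub = table[table["muscle"] == muscle].pivot_table(
                index="subject", columns=["task", "effort"], values=var
            )
            res = friedman_repeated(sub.to_numpy(), alpha=alpha)
            per_muscle[muscle] = {
                "chi2": res.chi2, "dof": res.dof, "p": res.p,
                "significant": bool(res.significant),
                "bonferroni_family": res.n_comparisons,
            }
        out[f"friedman_{var}"] = per_muscle

    # task (and task x effort) identification from intensity features
    out["classification"] = {}
    for feature in ("rms_av_hd", "rms_av_bip"):
        wide = norm.pivot_table(index=["subject", "task", "effort"],
                                columns="muscle", values=feature).reset_index()
        X = wide[muscles].to_numpy()
        for scheme in ("task", "task_effort"):
            y = (wide["task"] if scheme == "task"
                 else wide["task"] + "@" + wide["effort"].astype(str)).to_numpy()
            res = lda_loo(X, y)
            out["classification"][f"{feature}_{scheme}"] = {
                "accuracy": res.accuracy,
                "sensitivity": res.sensitivity,
                "specificity": res.specificity,
                "precision": res.precision,
                "n_classes": len(res.classes),
            }
    return out


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    n_subjects: int = 4,
    model: TaskModel | None = None,
    write_maps_for_subject: int | None = 0,
) -> dict:
    """Simulate, process and analyse a full task dataset; write artifacts
    under ``out_dir`` and return the statistics dictionary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = model or TaskModel()

    rows: list[dict] = []
    with _stage("process"):
        for record in iter_task_dataset(n_subjects, model.tasks, model.efforts,
                                        model, seed=config.seed):
            rows.extend(extract_condition_features(record, config))
            if write_maps_for_subject is not None and record.subject == write_maps_for_subject:
                for muscle, rec in record.recordings.items():
                    feats = channel_features(rec, config.epoching, mains_hz=config.mains_hz)
                    mask = classify_channels(feats, config.detector)
                    stem = out_dir / f"s{record.subject}_{record.task}_{record.effort_pct}_{muscle}"
                    write_qc_report(feats, mask, stem.with_suffix(".qc.tsv"))
                    write_map(compute_map(rec, 0, config.epoching, config.filter),
                              stem.with_suffix(".map.tsv"))

    with _stage("features"):
        table = pd.DataFrame(rows)
        table.to_csv(out_dir / "features.csv", index=False)

    with _stage("statistics"):
        stats = dataset_statistics(table)
        (out_dir / "stats.json").write_text(json.dumps(stats, indent=2))

    config.to_json(out_dir / "config.json")
    return stats
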