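"""End-to-end orchestration: preprocess -> segment -> phenotype -> evaluate.

A run is fully determined by its :class:`RunConfig` (every stage
parameter plus one seed); the config is serialized into the run directory
together with per-stage outputs, a phenotype CSV, an evaluation JSON and
a log of point counts, so a run can be reproduced or resumed stage by
stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import asdict, dataclass
from typing import List, Optional

import numpy as np
import pandas as pd
import yaml

from . import metrics as metrics_mod
from .cloud import CloudError, LabeledCloud
from .instancing import mean_shift_segment
from .io import read_cloud, write_cloud
from .phenotype import LeafPhenotype, PhenotypeConfig, PhenotypeError, estimate_phenotype
from .preprocess import denormalize, farthest_point_sample, normalize, remove_outliers, voxel_thin

__all__ = ["RunConfig", "run_pipeline", "preprocess_cloud", "phenotype_table"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters of one pipeline run (lengths in meters)."""

    input_path: str = ""
    output_dir: str = "run"
    # preprocessing
    sor_k: int = 16
    sor_std: float = 1.0
    voxel: float = 0.003
    fps_m: int = 2048
    cube_side: float = 2.0
    skip_fps: bool = False
    # instance segmentation
    radius: float = 0.045
    min_points: int = 10
    # phenotype estimation
    mls_radius: float = 0.012
    mls_order: int = 2
    midrib_k: int = 8
    tri_mu: float = 5.0
    tri_max_nn: int = 100
    min_leaf_points: int = 30
    # provenance
    seed: int = 0

    def phenotype_config(self) -> PhenotypeConfig:
        return PhenotypeConfig(
            mls_radius=self.mls_radius,
            mls_order=self.mls_order,
            midrib_k=self.midrib_k,
            tri_mu=self.tri_mu,
            tri_max_nn=self.tri_max_nn,
            min_points=self.min_leaf_points,
        )

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        if path.endswith(".toml"):
            import tomllib

            with open(path, "rb") as fh:
                data = tomllib.load(fh)
        else:
            with open(path) as fh:
                data = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def preprocess_cloud(cloud: LabeledCloud, cfg: RunConfig):
    """SOR -> voxel thinning -> FPS -> normalization; returns the
    normalized cloud, the transform, and per-stage point counts."""
    counts = {"input": cloud.n}
    cloud = remove_outliers(cloud, k=cfg.sor_k, std_ratio=cfg.sor_std)
    counts["after_sor"] = cloud.n
    cloud = voxel_thin(cloud, voxel=cfg.voxel)
    counts["after_voxel"] = cloud.n
    if not cfg.skip_fps:
        cloud = farthest_point_sample(cloud, m=cfg.fps_m, seed=cfg.seed)
    counts["after_fps"] = cloud.n
    normalized, transform = normalize(cloud, cube_side=cfg.cube_side)
    return normalized, transform, counts


def phenotype_table(
    cloud: LabeledCloud,
    cfg: RunConfig,
) -> pd.DataFrame:
    """Measure every leaf instance of an instanced cloud.

    Returns one row per instance: id, the four traits, point count and a
    status column ('ok' or the per-leaf failure message — a degenerate
    leaf does not abort the run).
    """
    if cloud.instance is None:
        raise CloudError("cloud has no instance labels; run segmentation first")
    rows = []
    pheno_cfg = cfg.phenotype_config()
    for inst in np.unique(cloud.instance):
        if inst < 0:
            continue
        pts = cloud.coords[cloud.instance == inst]
        try:
            ph = estimate_phenotype(pts, pheno_cfg, instance_id=int(inst))
            rows.append({
                "instance_id": int(inst),
                "inclination_deg": ph.inclination_deg,
                "length_cm": ph.length_cm,
                "width_cm": ph.width_cm,
                "area_cm2": ph.area_cm2,
                "n_points": ph.n_points,
                "status": "ok",
            })
        except PhenotypeError as exc:
            log.warning("skipping leaf %d: %s", int(inst), exc)
            rows.append({
                "instance_id": int(inst),
                "inclination_deg": np.nan,
                "length_cm": np.nan,
                "width_cm": np.nan,
                "area_cm2": np.nan,
                "n_points": int(pts.shape[0]),
                "status": str(exc),
            })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> str:
    """Run preprocess -> segment -> phenotype (-> evaluate, when the input
    carries ground-truth labels) and write all outputs to the run directory.

    Returns the run directory path.  Raises before creating any output if
    the input path is missing.
    """
    if not os.path.exists(config.input_path):
        raise FileNotFoundError(config.input_path)
    cloud = read_cloud(config.input_path)

    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    config.to_yaml(os.path.join(out, "config.yaml"))
    run_log: dict = {"seed": config.seed}

    normalized, transform, counts = preprocess_cloud(cloud, config)
    run_log["point_counts"] = counts
    restored = denormalize(normalized, transform)
    write_cloud(restored, os.path.join(out, "preprocessed.txt"))

    if restored.semantic is None:
        raise CloudError("input carries no semantic labels; cannot segment leaves")
    leaf = restored.leaf_points()
    result = mean_shift_segment(
        leaf, radius=config.radius, min_points=config.min_points
    )
    run_log["n_instances"] = int(result.n_instances)

    instanced = LabeledCloud(
        coords=restored.coords,
        semantic=restored.semantic,
        instance=np.full(restored.n, -1, dtype=np.int64),
    )
    instanced.instance[restored.semantic == 1] = result.instance
    write_cloud(instanced, os.path.join(out, "instanced.txt"))

    table = phenotype_table(instanced, config)
    table.to_csv(os.path.join(out, "phenotypes.csv"), index=False, float_format="%.6f")
    run_log["n_leaves_measured"] = int((table["status"] == "ok").sum())

    # evaluate predicted instances against ground truth when available
    if cloud.instance is not None:
        eval_report = _evaluate_against_truth(cloud, config, instanced)
        with open(os.path.join(out, "evaluation.json"), "w") as fh:
            json.dump(eval_report, fh, indent=2)
        run_log["evaluation"] = eval_report

    with open(os.path.join(out, "run_log.json"), "w") as fh:
        json.dump(run_log, fh, indent=2)
    return out


def _evaluate_against_truth(original: LabeledCloud, config: RunConfig, instanced: LabeledCloud) -> dict:
    """Re-segment the *original* labeled cloud and score instances against
    its ground-truth ids (preprocessing changes the point set, so the
    comparison runs on the unthinned points)."""
    leaf = original.leaf_points()
    pred = mean_shift_segment(leaf, radius=config.radius, min_points=config.min_points)
    true_sets = metrics_mod.instances_from_labels(leaf.instance)
    pred_sets = metrics_mod.instances_from_labels(pred.instance)
    report = metrics_mod.instance_pr(true_sets, pred_sets).as_dict()
    report["radius_m"] = config.radius
    return report
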