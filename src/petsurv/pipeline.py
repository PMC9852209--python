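"""End-to-end orchestration: simulate -> fit -> report.

``run_fit`` sequences the stages in their methodological order: preprocess
(smooth, then intensity-normalize, then mask to a feature matrix), discretize
survival into profiles, split 90/10, select voxels per class on the training
rows only (the non-leaky default), train the tuned one-vs-all SVMs, evaluate
on the holdout, and map each class's selected voxels to contiguous clusters.
Every run writes a manifest (config hash, seed, package version) and derives
per-stage sub-seeds from the global seed by stable hashing, so stages are
reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classify import baseline_knn, evaluate_holdout, split_train_test, train_ova
from .clusters import build_cluster_report
from .laplacian import class_aware_ranking
from .preproc import (
    BrainMask,
    assemble_features,
    gaussian_smooth,
    load_mask,
    load_volume,
    normalize_whole_brain,
    save_mask,
)
from .profiles import select_k
from .synthetic import (
    default_phantom_config,
    generate_cohort,
    generate_phantom_volumes,
    read_cohort_tsv,
    write_cohort_tsv,
    write_phantom,
)

log = logging.getLogger("petsurv")

__all__ = ["PipelineConfig", "run_simulate", "run_fit", "run_report", "stage_seed"]


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage sub-seed derived from the global seed."""
    digest = hashlib.sha256(f"{seed}/{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Everything a run needs; serializable to/from YAML."""

    # paths
    volumes_dir: str = "volumes"
    mask_path: str = "mask.nii.gz"
    cohort_path: str = "cohort.tsv"
    output_dir: str = "out"
    # preprocessing
    fwhm_mm: float = 10.0
    normalize: bool = True
    # discretization
    k_min: int = 2
    k_max: int = 6
    restarts: int = 20
    # selection
    n_neighbors: int = 5
    kernel_width: str | float = "auto"
    m: int = 400
    select_before_split: bool = False
    # classification
    budget: int = 50
    folds: int = 10
    test_fraction: float = 0.1
    search: str = "bayes"
    knn_baseline: bool = False
    # clustering
    min_extent: int = 100
    connectivity: int = 26
    # reproducibility
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_manifest(out: Path, config: PipelineConfig, extra: dict | None = None) -> None:
    payload = {
        "package": "petsurv",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        **(extra or {}),
    }
    (out / "manifest.json").write_text(json.dumps(payload, indent=1))


def run_simulate(
    config: PipelineConfig, n_subjects: int | None = None, preset: str = "clustered"
) -> Path:
    """Write a synthetic cohort (clinical TSV + phantom volumes) to disk."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = stage_seed(config.seed, "simulate")
    phantom_cfg = default_phantom_config(
        n_subjects=n_subjects or default_phantom_config().n_subjects, seed=seed
    )
    cohort = generate_cohort(preset, n=phantom_cfg.n_subjects, seed=seed)
    result = generate_phantom_volumes(phantom_cfg, cohort)
    write_cohort_tsv(cohort, out / "cohort.tsv")
    write_phantom(result, phantom_cfg, out)
    _write_manifest(out, config, {"stage": "simulate", "n_subjects": phantom_cfg.n_subjects})
    log.info("simulated %d subjects into %s", phantom_cfg.n_subjects, out)
    return out


def _preflight(config: PipelineConfig) -> None:
    missing = [
        str(p)
        for p in (Path(config.volumes_dir), Path(config.mask_path), Path(config.cohort_path))
        if not p.exists()
    ]
    if missing:
        raise FileNotFoundError(f"missing pipeline inputs: {missing}")


def run_fit(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the in-memory artifacts and writes them."""
    _preflight(config)
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    mask = load_mask(config.mask_path)
    cohort = read_cohort_tsv(config.cohort_path)
    vol_dir = Path(config.volumes_dir)
    volumes = []
    absent = []
    for sid in cohort["subject_id"]:
        matches = sorted(vol_dir.glob(f"{sid}.nii*"))
        if not matches:
            absent.append(str(sid))
            continue
        volumes.append(load_volume(matches[0], expected_shape=mask.shape))
    if absent:
        raise FileNotFoundError(f"missing volumes for subjects: {absent}")
    log.info("loaded %d volumes of shape %s", len(volumes), mask.shape)

    # --- preprocess: smooth, then normalize to whole-brain mean
    processed = []
    for vol in volumes:
        if config.fwhm_mm > 0:
            vol = gaussian_smooth(vol, config.fwhm_mm, mask=mask)
        if config.normalize:
            vol = normalize_whole_brain(vol, mask)
        processed.append(vol)
    fm = assemble_features(processed, mask)
    log.info("feature matrix: %d subjects x %d voxels", fm.n_subjects, fm.n_voxels)

    # --- discretize survival
    times = cohort["survival_years"].to_numpy(dtype=float)
    k, partition, criterion = select_k(
        times,
        k_range=range(config.k_min, config.k_max + 1),
        restarts=config.restarts,
        seed=stage_seed(config.seed, "discretize"),
    )
    partition.to_json(out / "partition.json")
    log.info("selected k=%d profiles, VE=%.3f", k, partition.ve)

    # --- split, select, train, evaluate
    idx = np.arange(fm.n_subjects)
    train_idx, test_idx = split_train_test(
        idx, partition.labels, test_fraction=config.test_fraction,
        seed=stage_seed(config.seed, "split"),
    )
    train_idx, test_idx = np.asarray(train_idx), np.asarray(test_idx)
    rank_rows = idx if config.select_before_split else train_idx
    rankings = {
        c: class_aware_ranking(
            fm.values[rank_rows], partition.labels[rank_rows], c,
            m=config.m, n_neighbors=config.n_neighbors, kernel_width=config.kernel_width,
        )
        for c in range(1, k + 1)
    }
    models = train_ova(
        fm.values[train_idx], partition.labels[train_idx], rankings,
        budget=config.budget, folds=config.folds,
        seed=stage_seed(config.seed, "tune"), method=config.search,
    )
    report = evaluate_holdout(models, fm.values[test_idx], partition.labels[test_idx])
    report.to_json(out / "eval.json")
    (out / "models.json").write_text(
        json.dumps([m.manifest() for m in models], indent=1)
    )
    if config.knn_baseline:
        knn_report = baseline_knn(
            fm.values[train_idx], partition.labels[train_idx], rankings,
            fm.values[test_idx], partition.labels[test_idx],
        )
        knn_report.to_json(out / "eval_knn.json")

    # --- map clusters per class
    cluster_frames = []
    for c in range(1, k + 1):
        selected_mask = np.zeros(fm.grid_shape, dtype=bool)
        selected_mask[tuple(fm.voxel_index[rankings[c].selected].T)] = True
        class_vols = [processed[i] for i in np.flatnonzero(partition.labels == c)]
        creport = build_cluster_report(
            c, selected_mask, fm.affine, class_vols,
            min_extent=config.min_extent, connectivity=config.connectivity,
        )
        cluster_frames.append(creport.to_frame())
        save_mask(
            BrainMask(data=selected_mask), fm.affine, out / f"selected_class{c}.nii.gz"
        )
        cmask = creport.cluster_mask(fm.grid_shape)
        if cmask.any():
            save_mask(BrainMask(data=cmask), fm.affine, out / f"clusters_class{c}.nii.gz")
    import pandas as pd

    cluster_table = pd.concat(cluster_frames, ignore_index=True)
    cluster_table.to_csv(out / "clusters.tsv", sep="\t", index=False)
    for c, r in rankings.items():
        r.to_tsv(out / f"ranking_class{c}.tsv", fm.voxel_index)

    _write_manifest(
        out, config,
        {"stage": "fit", "k": k, "ve": partition.ve, "wall_time_s": round(time.time() - t0, 2)},
    )
    log.info("fit finished in %.1f s", time.time() - t0)
    return {
        "partition": partition,
        "criterion": criterion,
        "rankings": rankings,
        "models": models,
        "eval": report,
        "clusters": cluster_table,
        "feature_matrix": fm,
    }


def run_report(output_dir: str | Path) -> str:
    """Consolidated human-readable summary of a finished fit."""
    out = Path(output_dir)
    needed = [out / "partition.json", out / "eval.json", out / "clusters.tsv"]
    missing = [str(p) for p in needed if not p.exists()]
    if missing:
        raise FileNotFoundError(f"missing fit artifacts: {missing}")
    partition = json.loads((out / "partition.json").read_text())
    eval_report = json.loads((out / "eval.json").read_text())
    import pandas as pd

    clusters = pd.read_csv(out / "clusters.tsv", sep="\t")
    lines = [
        f"Survival discretization: k={partition['k']}, VE={100 * partition['ve']:.1f}%",
        f"  boundaries (years): "
        + ", ".join(f"{b:.2f}" for b in (partition["boundaries"] or [])),
        "",
        "Per-class holdout performance (one-vs-all):",
        f"  {'class':>5} {'error%':>8} {'informedness':>13} {'c-stat':>7}",
    ]
    for c, row in sorted(eval_report.items()):
        if not row.get("defined", True):
            lines.append(f"  {c:>5}  (absent from test set)")
            continue
        lines.append(
            f"  {c:>5} {100 * row['error_rate']:>8.2f} "
            f"{row['informedness']:>13.3f} {row['c_statistic']:>7.3f}"
        )
    lines += ["", "Discriminant clusters (extent > threshold):"]
    if clusters.empty:
        lines.append("  none")
    else:
        lines.append(clusters.to_string(index=False))
    text = "\n".join(lines)
    (out / "report.txt").write_text(text)
    return text
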