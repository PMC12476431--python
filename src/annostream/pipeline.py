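"""End-to-end orchestration of one annotation-streamlining iteration.

One iteration runs: support-set patch selection from the labeled support
scans, patch-based inference over the query scans, prioritization of the
computed labels, simulated (or user-supplied) correction of the flagged
top-M scans, and export of the corrected + support scans as a supervised
training dataset (nnU-Net raw layout or flat pairs). Training itself is
external: typically a single iteration yields labels good enough that the
supervised model needs no further rounds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .correction_effort import (
    DetectionReport,
    EffortReport,
    aggregate_mean_std,
    detection_metrics,
    effort_metrics,
    match_lesions,
    simulate_correction,
)
from .inference_stitching import PatchSegmenter, resolve_segmenter, run_inference
from .preprocessing import (
    PipelineConfig,
    clip_and_normalize,
    extract_patches,
    filter_positive_patches,
)
from .prioritization import PrioritizedList, prioritize_scans
from .support_selection import (
    SupportSet,
    binarize_and_flatten,
    cluster_patches,
    select_support_clustering,
    select_support_random,
)
from .volume_model import LabelVolume, ScanVolume, write_volume

logger = logging.getLogger("annostream")


@dataclass
class IterationReport:
    """Everything one pipeline iteration produced."""

    iteration: int
    prioritized: PrioritizedList
    flagged_scan_ids: list[str]
    effort_by_scan: dict[str, EffortReport] = field(default_factory=dict)
    detection_by_scan: dict[str, DetectionReport] = field(default_factory=dict)
    aggregate_detection: dict[str, float] = field(default_factory=dict)
    aggregate_effort: dict[str, float] = field(default_factory=dict)
    corrected_dir: str | None = None
    export_dir: str | None = None


def build_support_set(
    support_pairs: list[tuple[ScanVolume, LabelVolume]], config: PipelineConfig
) -> SupportSet:
    """Normalize support scans, harvest positive patches, apply the policy."""
    candidates = []
    for scan, labels in support_pairs:
        norm = clip_and_normalize(scan, config.clip_lo, config.clip_hi)
        for s in range(norm.shape[0]):
            patches = extract_patches(
                norm.voxels[s],
                config.patch_size,
                config.stride,
                slice_index=s,
                label_pixels=labels.voxels[s],
                scan_id=scan.scan_id,
            )
            candidates.extend(patches)
    positive = filter_positive_patches(candidates, config.positivity_threshold)
    logger.info(
        "support pool: %d patches, %d positive (> %d pixels)",
        len(candidates),
        len(positive),
        config.positivity_threshold,
    )
    if not positive:
        raise ValueError("no positive patches in the support scans")
    if config.support_policy == "random":
        support = select_support_random(positive, config.support_budget, config.seed)
    elif config.support_policy == "clustering":
        vectors = np.stack([binarize_and_flatten(p) for p in positive])
        assignment = cluster_patches(
            vectors, config.n_clusters, config.seed, n_init=config.kmeans_restarts
        )
        support = select_support_clustering(
            assignment, positive, config.support_budget, config.seed
        )
    else:
        raise ValueError(f"unknown support policy {config.support_policy!r}")
    logger.info("selected %d support patches (%s policy)", len(support), support.policy)
    return support


def run_iteration(
    config: PipelineConfig,
    support_pairs: list[tuple[ScanVolume, LabelVolume]],
    query_scans: list[ScanVolume],
    gt_labels: dict[str, LabelVolume] | None = None,
    segmenter: PatchSegmenter | None = None,
    segmenter_factory: Callable[[ScanVolume], PatchSegmenter] | None = None,
    out_dir: str | Path | None = None,
    export_layout: str = "nnunet",
    iteration: int = 0,
) -> IterationReport:
    """Execute one full iteration of the annotation pipeline.

    In simulation mode (``gt_labels`` supplied) the flagged top-M scans are
    corrected by replacing their computed labels with ground truth, and
    detection/effort metrics are reported. Pass either a ready
    :class:`PatchSegmenter`, a per-scan ``segmenter_factory``, or neither to
    resolve ``config.segmenter`` from the registry (mock segmenters that
    answer from a reference volume then require ``gt_labels``).
    """
    support = build_support_set(support_pairs, config)

    def segmenter_for(scan: ScanVolume) -> PatchSegmenter:
        if segmenter_factory is not None:
            return segmenter_factory(scan)
        if segmenter is not None:
            return segmenter
        params = dict(config.segmenter_params)
        if config.segmenter in ("identity", "perturb"):
            if gt_labels is None or scan.scan_id not in gt_labels:
                raise ValueError(
                    f"segmenter {config.segmenter!r} answers from reference labels; "
                    f"none supplied for scan {scan.scan_id!r}"
                )
            params.setdefault("labels", gt_labels[scan.scan_id])
            if config.segmenter == "perturb":
                params.setdefault("seed", config.seed)
        return resolve_segmenter(config.segmenter, **params)

    computed: dict[str, LabelVolume] = {}
    for scan in query_scans:
        norm = clip_and_normalize(scan, config.clip_lo, config.clip_hi)
        labels = run_inference(norm, support, segmenter_for(scan), config)
        computed[scan.scan_id] = labels
        logger.info("inferred %s: %d foreground voxels", scan.scan_id, labels.foreground_count())

    prioritized = prioritize_scans(
        computed,
        config.n_correct,
        diameter_threshold_mm=config.diameter_threshold_mm,
        connectivity=config.connectivity,
        diameter_mode=config.diameter_mode,
    )
    flagged = prioritized.flagged
    logger.info("prioritized %d scans, flagged %s", len(computed), flagged)

    report = IterationReport(
        iteration=iteration, prioritized=prioritized, flagged_scan_ids=flagged
    )
    corrected: dict[str, LabelVolume] = {}
    if gt_labels is not None:
        for scan in query_scans:
            sid = scan.scan_id
            matching = match_lesions(computed[sid], gt_labels[sid], config.connectivity)
            report.detection_by_scan[sid] = detection_metrics(matching)
            if sid in flagged:
                fixed, effort = simulate_correction(
                    computed[sid], gt_labels[sid], config.connectivity
                )
                corrected[sid] = fixed
                report.effort_by_scan[sid] = effort
            else:
                report.effort_by_scan[sid] = effort_metrics(matching)
        for name in ("precision", "recall", "f1", "dice", "dice_with_fn"):
            mean, std = aggregate_mean_std(
                [getattr(r, name) for r in report.detection_by_scan.values()]
            )
            report.aggregate_detection[name] = mean
            report.aggregate_detection[name + "_std"] = std
        for name in ("fnr", "fpr", "ccs"):
            mean, std = aggregate_mean_std(
                [getattr(r, name) for r in report.effort_by_scan.values()]
            )
            report.aggregate_effort[name] = mean
            report.aggregate_effort[name + "_std"] = std

    if out_dir is not None:
        out_dir = Path(out_dir)
        if corrected:
            cdir = out_dir / "corrected"
            for sid, vol in corrected.items():
                write_volume(vol, cdir / f"{sid}.nii.gz")
            report.corrected_dir = str(cdir)
        export_items = [(s, l) for s, l in support_pairs]
        for scan in query_scans:
            if scan.scan_id in corrected:
                export_items.append((scan, corrected[scan.scan_id]))
        edir = export_supervised_dataset(
            export_items, out_dir / "export", layout=export_layout
        )
        report.export_dir = str(edir)
    return report


def export_supervised_dataset(
    pairs: list[tuple[ScanVolume, LabelVolume]],
    out_dir: str | Path,
    layout: str = "nnunet",
    dataset_name: str = "Dataset001_Lesions",
) -> Path:
    """Export scan/label pairs for supervised training; no training happens.

    ``nnunet`` layout writes the raw-dataset convention
    (``imagesTr/<id>_0000.nii.gz``, ``labelsTr/<id>.nii.gz``, and a
    ``dataset.json`` descriptor); ``flat`` writes side-by-side pairs plus a
    CSV manifest. Re-exporting the same pairs overwrites in place
    (idempotent); duplicate scan ids are an error.
    """
    ids = [s.scan_id for s, _ in pairs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate scan ids in export: {dupes}")
    out_dir = Path(out_dir)
    if layout == "nnunet":
        root = out_dir / dataset_name
        for scan, labels in pairs:
            write_volume(scan, root / "imagesTr" / f"{scan.scan_id}_0000.nii.gz")
            write_volume(labels, root / "labelsTr" / f"{scan.scan_id}.nii.gz")
        descriptor = {
            "channel_names": {"0": "image"},
            "labels": {"background": 0, "lesion": 1},
            "numTraining": len(pairs),
            "file_ending": ".nii.gz",
        }
        with open(root / "dataset.json", "w") as fh:
            json.dump(descriptor, fh, indent=2, sort_keys=True)
        return root
    if layout == "flat":
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for scan, labels in pairs:
            write_volume(scan, out_dir / f"{scan.scan_id}_image.nii.gz")
            write_volume(labels, out_dir / f"{scan.scan_id}_label.nii.gz")
            rows.append(
                {
                    "scan_id": scan.scan_id,
                    "image": f"{scan.scan_id}_image.nii.gz",
                    "label": f"{scan.scan_id}_label.nii.gz",
                }
            )
        pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
        return out_dir
    raise ValueError(f"unknown export layout {layout!r}")
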