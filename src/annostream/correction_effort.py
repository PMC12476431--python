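"""Lesion matching, detection/segmentation metrics, and correction-effort
estimation.

Matching is lesion-level with the one-voxel-overlap rule: a computed
component overlapping any ground-truth (GT) lesion is a true positive; a
computed component touching no GT lesion is a false positive; a GT lesion
touched by no computed component is a false negative. Several computed
components may overlap the same GT lesion — that lesion counts as detected
once, the extra components are not false positives (they do overlap GT) and
are merged into the pair's computed mask for Dice and contour scoring.

Correction effort is expressed in mouse clicks under the click model: one
click discards a false-positive lesion, one click marks a missed lesion, and
one click fixes each erroneous pixel on a matched lesion's contour. Three
ratios summarize it: FNR = FN / GT lesions, FPR = FP / GT lesions, and the
contour correction score CCS = erroneous contour pixels / GT contour pixels,
averaged over matched lesion pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .volume_model import Connectivity, LabelVolume, Lesion, find_lesions

NAN = float("nan")


def _is_missing(x: float) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass
class TPPair:
    """One detected GT lesion and the computed components covering it."""

    gt_lesion: Lesion
    computed_lesions: list[Lesion]

    def computed_slice_masks(self) -> dict[int, set[tuple[int, int]]]:
        """Per-slice pixel sets of the merged computed mask."""
        merged: dict[int, set[tuple[int, int]]] = {}
        for les in self.computed_lesions:
            for s, pix in les.slice_masks().items():
                merged.setdefault(s, set()).update(pix)
        return merged

    def computed_voxels(self) -> set[tuple[int, int, int]]:
        out: set[tuple[int, int, int]] = set()
        for les in self.computed_lesions:
            out |= les.voxel_coords
        return out

    def dice(self) -> float:
        a = self.computed_voxels()
        b = self.gt_lesion.voxel_coords
        return 2.0 * len(a & b) / (len(a) + len(b))


@dataclass
class LesionMatching:
    tp_pairs: list[TPPair]
    fp_lesions: list[Lesion]  # computed, zero GT overlap
    fn_lesions: list[Lesion]  # GT, zero computed overlap
    n_computed: int = 0
    n_gt: int = 0

    @property
    def n_tp(self) -> int:
        return len(self.tp_pairs)

    @property
    def n_fp(self) -> int:
        return len(self.fp_lesions)

    @property
    def n_fn(self) -> int:
        return len(self.fn_lesions)


@dataclass
class DetectionReport:
    """Lesion-detection and segmentation quality for one scan (or aggregate).

    ``dice`` averages per-pair Dice over matched pairs; ``dice_with_fn``
    averages over matched pairs plus FN and FP lesions, the unmatched ones
    scoring 0, so it degrades when detection is poor. Missing values (e.g.
    precision with no computed lesions) are NaN.
    """

    precision: float
    recall: float
    f1: float
    dice: float
    dice_with_fn: float
    n_tp: int = 0
    n_fp: int = 0
    n_fn: int = 0


@dataclass
class EffortReport:
    """Estimated manual-correction effort for one scan, in ratios and clicks."""

    fnr: float
    fpr: float
    ccs: float
    detection_clicks_fp: int
    detection_clicks_fn: int
    contour_clicks: int
    fn_delineation_clicks: int
    n_tp: int = 0
    n_fp: int = 0
    n_fn: int = 0
    n_gt: int = 0
    per_pair_ccs: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def match_lesions(
    computed: LabelVolume, gt: LabelVolume, connectivity: Connectivity = 26
) -> LesionMatching:
    """Pair computed and GT lesions by the one-voxel-overlap rule.

    A computed lesion overlapping several GT lesions is assigned to the GT
    lesion of largest overlap (ties: larger GT lesion, then lower GT
    component id).
    """
    if computed.shape != gt.shape:
        raise ValueError(f"shape mismatch: {computed.shape} vs {gt.shape}")
    comp_lesions = find_lesions(computed, connectivity=connectivity)
    gt_lesions = find_lesions(gt, connectivity=connectivity)
    assigned: dict[int, list[Lesion]] = {}
    fp: list[Lesion] = []
    for cl in comp_lesions:
        best_gt = None
        best_key = None
        for gl in gt_lesions:
            overlap = len(cl.voxel_coords & gl.voxel_coords)
            if overlap == 0:
                continue
            key = (-overlap, -gl.voxel_count, gl.component_id)
            if best_key is None or key < best_key:
                best_key = key
                best_gt = gl
        if best_gt is None:
            fp.append(cl)
        else:
            assigned.setdefault(best_gt.component_id, []).append(cl)
    # a GT lesion is detected if ANY computed lesion overlaps it, even one
    # whose largest overlap went to a different GT lesion
    touched: set[int] = set()
    for gl in gt_lesions:
        for cl in comp_lesions:
            if cl.voxel_coords & gl.voxel_coords:
                touched.add(gl.component_id)
                break
    tp_pairs = []
    fn = []
    for gl in gt_lesions:
        if gl.component_id in assigned:
            tp_pairs.append(TPPair(gt_lesion=gl, computed_lesions=assigned[gl.component_id]))
        elif gl.component_id in touched:
            # overlapped only by components assigned elsewhere: still detected,
            # pair it with those overlapping components for segmentation scoring
            overlapping = [cl for cl in comp_lesions if cl.voxel_coords & gl.voxel_coords]
            tp_pairs.append(TPPair(gt_lesion=gl, computed_lesions=overlapping))
        else:
            fn.append(gl)
    return LesionMatching(
        tp_pairs=tp_pairs,
        fp_lesions=fp,
        fn_lesions=fn,
        n_computed=len(comp_lesions),
        n_gt=len(gt_lesions),
    )


# ---------------------------------------------------------------------------
# Detection / segmentation metrics
# ---------------------------------------------------------------------------

def detection_metrics(matching: LesionMatching) -> DetectionReport:
    """Precision, recall, F1, Dice, and Dice-with-FN for one scan.

    Conventions for empty denominators: with neither computed nor GT lesions
    everything is 1 (nothing to find, nothing found); precision with no
    computed lesions is NaN; Dice with no matched pairs is NaN.
    """
    tp, fp, fn = matching.n_tp, matching.n_fp, matching.n_fn
    if matching.n_computed == 0 and matching.n_gt == 0:
        return DetectionReport(1.0, 1.0, 1.0, 1.0, 1.0, 0, 0, 0)
    precision = tp / (tp + fp) if (tp + fp) > 0 else NAN
    recall = tp / (tp + fn) if (tp + fn) > 0 else NAN
    if _is_missing(precision) or _is_missing(recall):
        f1 = NAN
    elif precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    pair_dice = [pair.dice() for pair in matching.tp_pairs]
    dice = float(np.mean(pair_dice)) if pair_dice else NAN
    all_dice = pair_dice + [0.0] * (fn + fp)
    dice_with_fn = float(np.mean(all_dice)) if all_dice else NAN
    return DetectionReport(precision, recall, f1, dice, dice_with_fn, tp, fp, fn)


# ---------------------------------------------------------------------------
# Correction effort
# ---------------------------------------------------------------------------

def _contour_of_slice_sets(
    slice_masks: dict[int, set[tuple[int, int]]]
) -> dict[int, set[tuple[int, int]]]:
    """4-neighbor in-slice contour of arbitrary per-slice pixel sets."""
    out: dict[int, set[tuple[int, int]]] = {}
    for s, pixels in slice_masks.items():
        out[s] = {
            (r, c)
            for (r, c) in pixels
            if any(
                (r + dr, c + dc) not in pixels
                for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1))
            )
        }
    return out


def pair_contour_errors(pair: TPPair) -> tuple[int, int]:
    """(erroneous pixels, GT contour pixels) for one matched pair.

    Erroneous pixels are the per-slice symmetric difference between the
    merged computed contour and the GT contour, summed over slices — the
    pixels a reader must add or delete to fix the delineation.
    """
    comp_contour = _contour_of_slice_sets(pair.computed_slice_masks())
    gt_contour = pair.gt_lesion.contour_pixels
    slices = set(comp_contour) | set(gt_contour)
    errors = sum(
        len(comp_contour.get(s, set()) ^ gt_contour.get(s, set())) for s in slices
    )
    gt_total = sum(len(p) for p in gt_contour.values())
    return errors, gt_total


def effort_metrics(matching: LesionMatching) -> EffortReport:
    """FNR, FPR, CCS, and the click counts for one scan.

    FN lesions' own contour pixels (the clicks needed to delineate a missed
    lesion from scratch) are reported separately as
    ``fn_delineation_clicks``; ``contour_clicks`` covers matched pairs only.
    With no GT lesions, FNR and FPR are NaN (undefined ratios).
    """
    n_gt = matching.n_gt
    fnr = matching.n_fn / n_gt if n_gt > 0 else NAN
    fpr = matching.n_fp / n_gt if n_gt > 0 else NAN
    per_pair = []
    contour_clicks = 0
    for pair in matching.tp_pairs:
        errors, gt_total = pair_contour_errors(pair)
        contour_clicks += errors
        per_pair.append(errors / gt_total if gt_total else NAN)
    ccs = float(np.nanmean(per_pair)) if per_pair else NAN
    fn_clicks = sum(
        sum(len(p) for p in les.contour_pixels.values()) for les in matching.fn_lesions
    )
    return EffortReport(
        fnr=fnr,
        fpr=fpr,
        ccs=ccs,
        detection_clicks_fp=matching.n_fp,
        detection_clicks_fn=matching.n_fn,
        contour_clicks=contour_clicks,
        fn_delineation_clicks=fn_clicks,
        n_tp=matching.n_tp,
        n_fp=matching.n_fp,
        n_fn=matching.n_fn,
        n_gt=n_gt,
        per_pair_ccs=per_pair,
    )


def simulate_correction(
    computed: LabelVolume, gt: LabelVolume, connectivity: Connectivity = 26
) -> tuple[LabelVolume, EffortReport]:
    """Replace the computed labels with the GT labels, reporting the effort
    the replacement would have cost under the click model."""
    if computed.shape != gt.shape:
        raise ValueError(f"shape mismatch: {computed.shape} vs {gt.shape}")
    matching = match_lesions(computed, gt, connectivity=connectivity)
    report = effort_metrics(matching)
    corrected = LabelVolume(
        gt.voxels.copy(), computed.spacing, computed.scan_id, computed.affine
    )
    return corrected, report


def percent_excess(larger: float, smaller: float) -> float:
    """Percent by which ``larger`` exceeds ``smaller``: 100 * (a - b) / b.

    Used to compare the correction effort of two scan-selection strategies
    (e.g. random vs prioritized click counts).
    """
    if smaller == 0:
        raise ZeroDivisionError("baseline count is zero")
    return 100.0 * (larger - smaller) / smaller


def aggregate_mean_std(values: list[float]) -> tuple[float, float]:
    """Mean and std over scans, ignoring missing (NaN) entries."""
    arr = np.asarray([v for v in values if not _is_missing(v)], dtype=float)
    if arr.size == 0:
        return NAN, NAN
    return float(arr.mean()), float(arr.std())
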