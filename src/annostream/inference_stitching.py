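"""Patch-segmenter seam, slice stitching, and volume postprocessing.

A :class:`PatchSegmenter` maps (query patch, support set) to a P x P
foreground-score grid in [0, 1]; the actual few-shot model sits behind this
interface and the package ships deterministic mocks for it. Overlapping
patch scores are combined per pixel by their mean and thresholded at 0.5
(ties count as foreground), which makes decomposition + stitching an exact
round trip for any segmenter that reproduces its input labels. Assembled
volumes are postprocessed by filling enclosed background cavities and
removing components of at most ``min_lesion_voxels`` voxels.
"""

from __future__ import annotations

from typing import Callable, Protocol

import numpy as np
from scipy import ndimage

from .preprocessing import PipelineConfig, SlicePatch, extract_patches
from .support_selection import SupportSet
from .volume_model import _STRUCTS, Connectivity, LabelVolume, ScanVolume


class PatchSegmenter(Protocol):
    """Behavioral contract for pluggable patch segmenters."""

    def __call__(self, patch: SlicePatch, support: SupportSet) -> np.ndarray:
        """Return a P x P foreground-score grid in [0, 1]."""
        ...


# ---------------------------------------------------------------------------
# Mock segmenters (registry)
# ---------------------------------------------------------------------------

SEGMENTER_REGISTRY: dict[str, Callable[..., PatchSegmenter]] = {}


def register_segmenter(name: str):
    def deco(factory):
        SEGMENTER_REGISTRY[name] = factory
        return factory
    return deco


def resolve_segmenter(name: str, **params) -> PatchSegmenter:
    try:
        factory = SEGMENTER_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown segmenter {name!r}; registered: {sorted(SEGMENTER_REGISTRY)}"
        ) from None
    return factory(**params)


def _crop_volume_patch(volume: np.ndarray, patch: SlicePatch) -> np.ndarray:
    """Crop the volume window under ``patch`` (zero-padded past the edges)."""
    s, r, c = patch.origin
    size = patch.size
    out = np.zeros((size, size), dtype=np.float64)
    sl = volume[s]
    r_end = min(r + size, sl.shape[0])
    c_end = min(c + size, sl.shape[1])
    out[: r_end - r, : c_end - c] = sl[r:r_end, c:c_end]
    return out


@register_segmenter("identity")
def make_identity_segmenter(labels: LabelVolume) -> PatchSegmenter:
    """Oracle segmenter answering every query from a reference label volume."""
    vol = labels.voxels.astype(np.float64)

    def segment(patch: SlicePatch, support: SupportSet) -> np.ndarray:
        return _crop_volume_patch(vol, patch)

    return segment


@register_segmenter("constant")
def make_constant_segmenter(value: float = 0.0) -> PatchSegmenter:
    """Segmenter returning a constant score everywhere (e.g. 0 = all background)."""

    def segment(patch: SlicePatch, support: SupportSet) -> np.ndarray:
        return np.full_like(patch.pixels, float(value), dtype=np.float64)

    return segment


# the "perturb" mock lives in synthetic_fixtures (it needs the phantom GT);
# it registers itself on import.


# ---------------------------------------------------------------------------
# Stitching
# ---------------------------------------------------------------------------

def stitch_slice(
    patch_scores: list[tuple[tuple[int, int], np.ndarray]],
    slice_shape: tuple[int, int],
    mode: str = "mean",
) -> np.ndarray:
    """Combine overlapping patch score grids into one binary slice mask.

    ``mean`` mode averages all covering scores per pixel and thresholds at
    0.5 (>= 0.5 is foreground); ``or`` mode marks a pixel foreground if any
    covering patch scores it >= 0.5 (for binary-only segmenters).
    Raises if any pixel is covered by no patch.
    """
    acc = np.zeros(slice_shape, dtype=np.float64)
    cnt = np.zeros(slice_shape, dtype=np.int64)
    hit = np.zeros(slice_shape, dtype=bool)
    for (r, c), scores in patch_scores:
        scores = np.asarray(scores, dtype=np.float64)
        size = scores.shape[0]
        r_end = min(r + size, slice_shape[0])
        c_end = min(c + size, slice_shape[1])
        window = scores[: r_end - r, : c_end - c]
        if mode == "or":
            hit[r:r_end, c:c_end] |= window >= 0.5
        else:
            acc[r:r_end, c:c_end] += window
        cnt[r:r_end, c:c_end] += 1
    if (cnt == 0).any():
        raise ValueError("stitching left uncovered pixels; patch grid is broken")
    if mode == "or":
        return hit.astype(np.uint8)
    return (acc / cnt >= 0.5).astype(np.uint8)


def assemble_volume(
    slice_masks: list[np.ndarray],
    spacing: tuple[float, float, float],
    scan_id: str = "",
    affine: np.ndarray | None = None,
) -> LabelVolume:
    """Stack per-slice binary masks into a 3D label volume."""
    shapes = {m.shape for m in slice_masks}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent slice shapes: {shapes}")
    return LabelVolume(np.stack(slice_masks).astype(np.uint8), spacing, scan_id, affine)


def postprocess_labels(
    labels: LabelVolume,
    min_lesion_voxels: int = 30,
    connectivity: Connectivity = 26,
    hole_fill: str = "3d",
) -> LabelVolume:
    """Fill enclosed background cavities, then drop small components.

    Filling runs first so removal is decided on final component sizes; a
    component is removed iff its voxel count is <= ``min_lesion_voxels``.
    ``hole_fill`` may be ``"3d"`` (default), ``"2d"`` (per axial slice), or
    ``"off"``.
    """
    mask = labels.voxels > 0
    if hole_fill == "3d":
        mask = ndimage.binary_fill_holes(mask)
    elif hole_fill == "2d":
        mask = np.stack([ndimage.binary_fill_holes(sl) for sl in mask])
    elif hole_fill != "off":
        raise ValueError(f"unknown hole_fill mode {hole_fill!r}")
    labeled, n = ndimage.label(mask, structure=_STRUCTS[connectivity])
    if n:
        counts = np.bincount(labeled.ravel())
        keep = counts > min_lesion_voxels
        keep[0] = False
        mask = keep[labeled]
    return LabelVolume(
        mask.astype(np.uint8), labels.spacing, labels.scan_id, labels.affine
    )


def run_inference(
    scan: ScanVolume,
    support: SupportSet,
    segmenter: PatchSegmenter,
    config: PipelineConfig,
    postprocess: bool = True,
) -> LabelVolume:
    """Segment a (normalized) scan slice by slice and assemble the 3D labels.

    Per slice: extract the half-stride patch grid, score each patch with the
    segmenter conditioned on the support set, stitch, and finally stack and
    postprocess. Deterministic whenever the segmenter is.
    """
    masks = []
    n_rows, n_cols = scan.shape[1], scan.shape[2]
    for s in range(scan.shape[0]):
        patches = extract_patches(
            scan.voxels[s],
            config.patch_size,
            config.stride,
            slice_index=s,
            scan_id=scan.scan_id,
        )
        scored = [
            ((p.origin[1], p.origin[2]), segmenter(p, support)) for p in patches
        ]
        masks.append(stitch_slice(scored, (n_rows, n_cols), mode=config.stitch_mode))
    volume = assemble_volume(masks, scan.spacing, scan.scan_id, scan.affine)
    if postprocess:
        volume = postprocess_labels(
            volume,
            min_lesion_voxels=config.min_lesion_voxels,
            connectivity=config.connectivity,
            hole_fill=config.hole_fill,
        )
    return volume
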