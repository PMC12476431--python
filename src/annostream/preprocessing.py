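"""Intensity normalization and sliding-window slice-patch extraction.

Scans are clipped to a preset intensity window and min-max scaled to [0, 1];
each axial slice is then decomposed into P x P patches on a half-stride grid
(default 128 with stride 64) so that every pixel is covered by at least one
patch. Patches whose label window holds more than ``positivity_threshold``
positive pixels are the candidates for the support set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .volume_model import Connectivity, DiameterMode, ScanVolume


@dataclass
class SlicePatch:
    """A P x P window of one scan slice, optionally with its label window.

    ``origin`` is ``(slice_index, row_offset, col_offset)`` of the patch's
    top-left pixel within the (zero-padded) slice.
    """

    pixels: np.ndarray
    origin: tuple[int, int, int]
    scan_id: str = ""
    label_pixels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError(f"patch must be square 2D, got {self.pixels.shape}")
        if any(o < 0 for o in self.origin):
            raise ValueError(f"origin must be non-negative, got {self.origin}")
        if self.label_pixels is not None:
            self.label_pixels = np.asarray(self.label_pixels).astype(np.uint8)
            if self.label_pixels.shape != self.pixels.shape:
                raise ValueError("label window shape must match the pixel window")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    def positive_count(self) -> int:
        if self.label_pixels is None:
            raise ValueError("patch has no label window")
        return int(self.label_pixels.sum())


@dataclass
class PipelineConfig:
    """Every tunable the pipeline reads, with the defaults used throughout.

    Attributes
    ----------
    clip_lo, clip_hi : float
        Intensity clipping window (default a CT soft-tissue-like window).
    patch_size : int
        Patch side P in pixels (default 128).
    stride : int
        Patch grid stride; default P/2 = 64 (half-stride overlap).
    positivity_threshold : int
        A patch is "positive" iff its label window has strictly more than
        this many foreground pixels (default 30).
    min_lesion_voxels : int
        Components with voxel count <= this are removed in postprocessing
        (default 30, roughly a 3 mm lesion at 1 mm isotropic spacing).
    diameter_threshold_mm : float
        A lesion is "large" iff its diameter is >= this (default 10 mm).
    support_budget : int
        Number of patches in the support set (default 450).
    n_clusters : int
        k for the k-means support-selection policy (default 100).
    n_correct : int
        Number of prioritized scans flagged for manual correction
        (default 10; typical practice is 10-30).
    """

    clip_lo: float = -100.0
    clip_hi: float = 200.0
    patch_size: int = 128
    stride: int = 64
    positivity_threshold: int = 30
    min_lesion_voxels: int = 30
    diameter_threshold_mm: float = 10.0
    support_budget: int = 450
    n_clusters: int = 100
    n_correct: int = 10
    seed: int = 0
    connectivity: Connectivity = 26
    diameter_mode: DiameterMode = "equivalent_sphere"
    support_policy: str = "clustering"  # or "random"
    segmenter: str = "identity"
    stitch_mode: str = "mean"  # "mean" (threshold 0.5) or "or"
    hole_fill: str = "3d"  # "3d", "2d", or "off"
    kmeans_restarts: int = 10
    segmenter_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.clip_lo >= self.clip_hi:
            raise ValueError("clip_lo must be < clip_hi")
        if not (0 < self.stride <= self.patch_size):
            raise ValueError("stride must satisfy 0 < stride <= patch_size")
        if self.support_budget < 1:
            raise ValueError("support_budget must be >= 1")
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.n_correct < 1:
            raise ValueError("n_correct must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def clip_and_normalize(scan: ScanVolume, clip_lo: float, clip_hi: float) -> ScanVolume:
    """Clip intensities to ``[clip_lo, clip_hi]`` and min-max scale to [0, 1].

    The affine map sends the post-clip minimum to 0 and maximum to 1; a
    constant volume maps to all zeros.
    """
    if clip_lo >= clip_hi:
        raise ValueError("clip_lo must be < clip_hi")
    vox = np.asarray(scan.voxels, dtype=np.float64)
    if not np.isfinite(vox).all():
        raise ValueError("scan contains non-finite voxels")
    clipped = np.clip(vox, clip_lo, clip_hi)
    lo, hi = clipped.min(), clipped.max()
    if hi > lo:
        out = (clipped - lo) / (hi - lo)
    else:
        out = np.zeros_like(clipped)
    return ScanVolume(out, scan.spacing, scan.scan_id, scan.affine)


# ---------------------------------------------------------------------------
# Patch grids
# ---------------------------------------------------------------------------

def patch_origins(dim: int, patch: int, stride: int) -> list[int]:
    """1D origins: multiples of ``stride`` with an extra edge-aligned origin
    appended when the regular grid stops short of the edge."""
    if dim <= patch:
        return [0]
    origins = list(range(0, dim - patch + 1, stride))
    if origins[-1] != dim - patch:
        origins.append(dim - patch)
    return origins


def extract_patches(
    slice_pixels: np.ndarray,
    patch_size: int,
    stride: int,
    slice_index: int = 0,
    label_pixels: np.ndarray | None = None,
    scan_id: str = "",
) -> list[SlicePatch]:
    """Decompose one slice into P x P patches covering every pixel.

    Slices smaller than P are zero-padded on the bottom/right before
    windowing, so a small slice yields exactly one patch at (0, 0).
    """
    arr = np.asarray(slice_pixels)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D slice, got shape {arr.shape}")
    pad_r = max(0, patch_size - arr.shape[0])
    pad_c = max(0, patch_size - arr.shape[1])
    if pad_r or pad_c:
        arr = np.pad(arr, ((0, pad_r), (0, pad_c)))
        if label_pixels is not None:
            label_pixels = np.pad(np.asarray(label_pixels), ((0, pad_r), (0, pad_c)))
    rows = patch_origins(arr.shape[0], patch_size, stride)
    cols = patch_origins(arr.shape[1], patch_size, stride)
    patches = []
    for r in rows:
        for c in cols:
            lab = None
            if label_pixels is not None:
                lab = np.asarray(label_pixels)[r : r + patch_size, c : c + patch_size]
            patches.append(
                SlicePatch(
                    pixels=arr[r : r + patch_size, c : c + patch_size],
                    origin=(slice_index, r, c),
                    scan_id=scan_id,
                    label_pixels=lab,
                )
            )
    return patches


def filter_positive_patches(
    patches: list[SlicePatch], positivity_threshold: int = 30
) -> list[SlicePatch]:
    """Keep patches with strictly more than ``positivity_threshold`` positive
    label pixels."""
    return [p for p in patches if p.positive_count() > positivity_threshold]


def reconstruct_coverage_map(
    patches: list[SlicePatch], slice_shape: tuple[int, int]
) -> np.ndarray:
    """Per-pixel count of covering patches (within the unpadded slice)."""
    counts = np.zeros(slice_shape, dtype=np.int64)
    for p in patches:
        _, r, c = p.origin
        counts[r : r + p.size, c : c + p.size] += 1
    return counts
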