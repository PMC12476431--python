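"""Synthetic phantoms and mock segmenters.

The phantom generator emulates the pipeline's target setting — scans bearing
many small ellipsoidal lesions, a minority at or above the 10 mm large-lesion
threshold, on a noisy CT-like intensity background — so that every stage and
every metric can be exercised, and parameters recovered, without any real
data. The perturbed mock segmenter answers patch queries from a corrupted
copy of the ground truth with controllable false-negative probability,
false-positive rate, and boundary jitter, standing in for an imperfect
few-shot model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .inference_stitching import (
    PatchSegmenter,
    _crop_volume_patch,
    register_segmenter,
)
from .preprocessing import SlicePatch
from .support_selection import SupportSet
from .volume_model import LabelVolume, ScanVolume, find_lesions, write_volume


@dataclass
class PhantomSpec:
    """Parameters of one synthetic scan/label pair.

    Defaults give a 96 x 96 x 40-voxel scan at 1 mm isotropic spacing with
    20 pairwise-disjoint ellipsoidal lesions (the per-scan lesion load of a
    typical metastatic liver study), diameters 4-14 mm with 30% drawn at or
    above 10 mm, a CT-soft-tissue-like background of 40 intensity units,
    +60 units of lesion contrast, and additive Gaussian noise of sigma 10.
    """

    shape: tuple[int, int, int] = (40, 96, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_lesions: int = 20
    diameter_range_mm: tuple[float, float] = (4.0, 14.0)
    frac_large: float = 0.3
    large_threshold_mm: float = 10.0
    axis_ratio_range: tuple[float, float] = (0.8, 1.25)
    background_intensity: float = 40.0
    lesion_contrast: float = 60.0
    noise_sigma: float = 10.0
    min_voxels: int = 31  # every lesion strictly above the 30-voxel removal rule
    margin_voxels: int = 2  # minimum gap between lesions (keeps components disjoint)
    seed: int = 0


@dataclass
class PerturbationSpec:
    """Corruption applied to ground truth to mock an imperfect segmenter.

    ``p_fn`` drops each GT lesion independently; ``fp_rate`` is the expected
    (Poisson) number of spurious blobs per scan, placed away from GT lesions
    and sized above the small-component removal threshold so postprocessing
    does not silently erase them; ``boundary_jitter`` is a signed
    morphological radius range in voxels (positive dilates, negative erodes),
    drawn per surviving lesion.
    """

    p_fn: float = 0.0
    fp_rate: float = 0.0
    boundary_jitter: tuple[int, int] = (0, 0)
    fp_diameter_range_mm: tuple[float, float] = (5.0, 8.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_fn <= 1.0):
            raise ValueError("p_fn must be in [0, 1]")
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be >= 0")


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center: tuple[float, float, float],
    semi_axes_mm: tuple[float, float, float],
) -> np.ndarray:
    """Voxelized ellipsoid: voxel centers within the physical ellipsoid."""
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    q = np.zeros(shape, dtype=np.float64)
    for g, ctr, sp, ax in zip(grids, center, spacing, semi_axes_mm):
        q = q + (((g - ctr) * sp) / ax) ** 2
    return q <= 1.0


def generate_phantom(
    spec: PhantomSpec, scan_id: str = "phantom"
) -> tuple[ScanVolume, LabelVolume, pd.DataFrame]:
    """Generate one synthetic scan, its ground-truth labels, and a manifest.

    Lesion diameters are drawn below/above ``large_threshold_mm`` according
    to ``frac_large``; ellipsoid semi-axes preserve the equivalent-sphere
    diameter (their geometric mean is the radius). Placement is by rejection
    sampling against overlap with previously placed lesions. Deterministic
    per seed.
    """
    rng = np.random.default_rng(spec.seed)
    shape, spacing = spec.shape, spec.spacing
    labels = np.zeros(shape, dtype=np.uint8)
    blocked = np.zeros(shape, dtype=bool)  # lesions + margin
    margin_struct = ndimage.generate_binary_structure(3, 3)
    rows = []
    lo, hi = spec.diameter_range_mm
    thr = spec.large_threshold_mm
    for i in range(spec.n_lesions):
        placed = False
        for _attempt in range(300):
            if rng.random() < spec.frac_large and hi >= thr:
                diameter = rng.uniform(max(lo, thr), hi)
            else:
                diameter = rng.uniform(lo, min(hi, thr))
            u = rng.uniform(*spec.axis_ratio_range)
            v = rng.uniform(*spec.axis_ratio_range)
            r = diameter / 2.0
            axes = (r * u, r * v, r / (u * v))
            if any(
                ax / sp + 1 >= dim - ax / sp - 1
                for dim, sp, ax in zip(shape, spacing, axes)
            ):
                continue  # lesion too large for this grid; redraw
            center = tuple(
                rng.uniform(ax / sp + 1, dim - ax / sp - 1)
                for dim, sp, ax in zip(shape, spacing, axes)
            )
            mask = _ellipsoid_mask(shape, spacing, center, axes)
            count = int(mask.sum())
            if count <= max(0, spec.min_voxels - 1):
                continue
            if (mask & blocked).any():
                continue
            labels[mask] = 1
            blocked |= ndimage.binary_dilation(
                mask, structure=margin_struct, iterations=max(1, spec.margin_voxels)
            )
            voxel_vol = float(np.prod(spacing))
            rows.append(
                {
                    "lesion_index": i,
                    "center_slice": center[0],
                    "center_row": center[1],
                    "center_col": center[2],
                    "axis_mm_0": axes[0],
                    "axis_mm_1": axes[1],
                    "axis_mm_2": axes[2],
                    "requested_diameter_mm": diameter,
                    "voxel_count": count,
                    "equiv_diameter_mm": 2.0
                    * (3.0 * count * voxel_vol / (4.0 * np.pi)) ** (1.0 / 3.0),
                }
            )
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place lesion {i} after 300 attempts; "
                "reduce n_lesions or diameters, or enlarge the grid"
            )
    intensity = np.full(shape, spec.background_intensity, dtype=np.float64)
    intensity += spec.lesion_contrast * labels
    intensity += rng.normal(0.0, spec.noise_sigma, size=shape)
    scan = ScanVolume(intensity, spacing, scan_id)
    gt = LabelVolume(labels, spacing, scan_id)
    manifest = pd.DataFrame(rows)
    return scan, gt, manifest


# ---------------------------------------------------------------------------
# Perturbed ground truth / mock segmenter
# ---------------------------------------------------------------------------

def perturb_labels(gt: LabelVolume, spec: PerturbationSpec) -> LabelVolume:
    """Corrupt a GT label volume per the perturbation spec (seeded)."""
    rng = np.random.default_rng(spec.seed)
    out = np.zeros(gt.shape, dtype=bool)
    struct = ndimage.generate_binary_structure(3, 1)
    lesions = find_lesions(gt)
    jitter_lo, jitter_hi = spec.boundary_jitter
    for les in lesions:
        if rng.random() < spec.p_fn:
            continue
        mask = np.zeros(gt.shape, dtype=bool)
        idx = tuple(np.array(sorted(les.voxel_coords)).T)
        mask[idx] = True
        r = int(rng.integers(jitter_lo, jitter_hi + 1)) if jitter_hi >= jitter_lo else 0
        if r > 0:
            mask = ndimage.binary_dilation(mask, structure=struct, iterations=r)
        elif r < 0:
            mask = ndimage.binary_erosion(mask, structure=struct, iterations=-r)
        out |= mask
    n_fp = int(rng.poisson(spec.fp_rate))
    forbidden = ndimage.binary_dilation(
        gt.voxels > 0, structure=ndimage.generate_binary_structure(3, 3), iterations=2
    )
    for _ in range(n_fp):
        for _attempt in range(300):
            d = rng.uniform(*spec.fp_diameter_range_mm)
            r_mm = d / 2.0
            center = tuple(
                rng.uniform(r_mm / sp + 1, dim - r_mm / sp - 1)
                for dim, sp in zip(gt.shape, gt.spacing)
            )
            blob = _ellipsoid_mask(gt.shape, gt.spacing, center, (r_mm, r_mm, r_mm))
            if blob.sum() <= 30:
                continue
            # dilate before the collision test so separate blobs cannot
            # touch and merge into one component
            grown = ndimage.binary_dilation(
                blob, structure=ndimage.generate_binary_structure(3, 3)
            )
            if (grown & forbidden).any() or (grown & out).any():
                continue
            out |= blob
            break
    return LabelVolume(out.astype(np.uint8), gt.spacing, gt.scan_id, gt.affine)


@register_segmenter("perturb")
def make_perturbed_segmenter(
    labels: LabelVolume,
    p_fn: float = 0.0,
    fp_rate: float = 0.0,
    boundary_jitter: tuple[int, int] = (0, 0),
    fp_diameter_range_mm: tuple[float, float] = (5.0, 8.0),
    seed: int = 0,
) -> PatchSegmenter:
    """Mock segmenter answering queries from a perturbed copy of the GT."""
    spec = PerturbationSpec(
        p_fn=p_fn,
        fp_rate=fp_rate,
        boundary_jitter=tuple(boundary_jitter),  # type: ignore[arg-type]
        fp_diameter_range_mm=tuple(fp_diameter_range_mm),  # type: ignore[arg-type]
        seed=seed,
    )
    perturbed = perturb_labels(labels, spec).voxels.astype(np.float64)

    def segment(patch: SlicePatch, support: SupportSet) -> np.ndarray:
        return _crop_volume_patch(perturbed, patch)

    return segment


# ---------------------------------------------------------------------------
# On-disk study fixtures
# ---------------------------------------------------------------------------

def build_study_fixture(
    n_scans: int,
    out_dir: str | Path,
    phantom_spec: PhantomSpec | None = None,
    overwrite: bool = False,
    prefix: str = "scan",
) -> pd.DataFrame:
    """Write ``n_scans`` scan/label NIfTI pairs plus a combined manifest.

    Scan ids are ``scan_000`` ... with per-scan seeds derived from the spec
    seed, so regeneration is byte-identical. Refuses to write into an
    existing non-empty directory unless ``overwrite`` is set.
    """
    spec = phantom_spec or PhantomSpec()
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} exists and is not empty")
    (out_dir / "scans").mkdir(parents=True, exist_ok=True)
    (out_dir / "labels").mkdir(parents=True, exist_ok=True)
    manifests = []
    for i in range(n_scans):
        scan_id = f"{prefix}_{i:03d}"
        sub = PhantomSpec(**{**spec.__dict__, "seed": (spec.seed * 10007 + i) % (2**31)})
        scan, gt, manifest = generate_phantom(sub, scan_id=scan_id)
        write_volume(scan, out_dir / "scans" / f"{scan_id}.nii.gz")
        write_volume(gt, out_dir / "labels" / f"{scan_id}.nii.gz")
        manifest.insert(0, "scan_id", scan_id)
        manifests.append(manifest)
    combined = pd.concat(manifests, ignore_index=True)
    combined.to_csv(out_dir / "manifest.csv", index=False)
    return combined
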