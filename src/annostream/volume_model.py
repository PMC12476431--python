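"""Core volumetric data types: scans, binary label volumes, and lesions.

A *lesion* is one 3D connected component of a binary label volume. All
volumes use the in-memory axis convention ``(slice, row, col)`` with the
slice axis being the axial axis as stored on disk; ``spacing`` is the
physical voxel size in mm, ordered to match the array axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import nibabel as nib
import numpy as np
from scipy import ndimage

Connectivity = Literal[6, 18, 26]
DiameterMode = Literal["equivalent_sphere", "max_inplane"]

#: scipy structuring elements for the three standard 3D connectivities.
_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class ScanVolume:
    """A 3D intensity volume with physical spacing.

    Parameters
    ----------
    voxels : ndarray, shape (n_slices, n_rows, n_cols)
        Intensity grid in arbitrary units.
    spacing : tuple of float
        Voxel size in mm per axis, same order as the array axes.
    scan_id : str
        Identifier carried through the pipeline.
    affine : ndarray or None
        Opaque orientation metadata passed through to NIfTI output.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    scan_id: str = ""
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.voxels.shape}")
        if min(self.voxels.shape) < 1:
            raise ValueError("each axis needs at least one voxel")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive mm values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class LabelVolume(ScanVolume):
    """A binary lesion mask aligned voxel-for-voxel with a :class:`ScanVolume`."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vox = np.asarray(self.voxels)
        if vox.dtype != np.uint8 or not np.isin(vox, (0, 1)).all():
            uniq = np.unique(vox)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError(f"label volume must be binary, found values {uniq[:10]}")
        self.voxels = vox.astype(np.uint8, copy=False)

    def foreground_count(self) -> int:
        return int(self.voxels.sum())


@dataclass
class Lesion:
    """One 3D connected component of a label volume.

    ``voxel_coords`` are ``(slice, row, col)`` indices; ``contour_pixels``
    maps slice index to the set of in-slice boundary pixels (see
    :func:`lesion_contours`).
    """

    component_id: int
    voxel_coords: set[tuple[int, int, int]]
    voxel_count: int
    volume_mm3: float
    diameter_mm: float
    contour_pixels: dict[int, set[tuple[int, int]]] = field(default_factory=dict)

    def slice_masks(self) -> dict[int, set[tuple[int, int]]]:
        """Per-slice sets of (row, col) pixels belonging to this lesion."""
        out: dict[int, set[tuple[int, int]]] = {}
        for s, r, c in self.voxel_coords:
            out.setdefault(s, set()).add((r, c))
        return out


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | Path, kind: Literal["scan", "label"] = "scan") -> ScanVolume:
    """Read a NIfTI volume; for ``kind='label'`` binarize by value > 0.

    The on-disk NIfTI axis order ``(i, j, k)`` is reversed so that the slice
    axis comes first in memory; spacing is reversed to match.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {data.shape}")
    data = np.transpose(data, (2, 1, 0))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])[::-1]
    scan_id = path.name.removesuffix(".gz").removesuffix(".nii")
    if kind == "label":
        if not np.isfinite(data).all():
            raise ValueError(f"{path}: non-finite label values")
        uniq = np.unique(data)
        if not np.all(np.isin(uniq, (0, 1))):
            warnings.warn(
                f"{path}: label values {uniq[:10]} binarized by > 0", stacklevel=2
            )
        return LabelVolume((data > 0).astype(np.uint8), spacing, scan_id, img.affine)
    return ScanVolume(data.astype(np.float64), spacing, scan_id, img.affine)


def write_volume(volume: ScanVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI, inverting the axis convention of :func:`read_volume`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.transpose(volume.voxels, (2, 1, 0))
    if volume.affine is not None:
        affine = volume.affine
    else:
        affine = np.diag([*volume.spacing[::-1], 1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms(volume.spacing[::-1])
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Lesion extraction and geometry
# ---------------------------------------------------------------------------

def find_lesions(
    labels: LabelVolume,
    connectivity: Connectivity = 26,
    diameter_mode: DiameterMode = "equivalent_sphere",
) -> list[Lesion]:
    """Extract 3D connected components as :class:`Lesion` objects.

    Lesions are ordered by descending voxel count; ties break by the first
    foreground voxel in scan (C) order. Component ids are assigned after
    sorting, starting at 1.
    """
    mask = labels.voxels > 0
    if not mask.any():
        return []
    labeled, n = ndimage.label(mask, structure=_STRUCTS[connectivity])
    objects = ndimage.find_objects(labeled)
    voxel_vol = labels.voxel_volume_mm3
    raw: list[tuple[int, int, set[tuple[int, int, int]]]] = []
    flat = labeled.ravel()
    for lab in range(1, n + 1):
        sl = objects[lab - 1]
        sub = labeled[sl] == lab
        coords = {
            (int(s + sl[0].start), int(r + sl[1].start), int(c + sl[2].start))
            for s, r, c in zip(*np.nonzero(sub))
        }
        first = int(np.argmax(flat == lab))
        raw.append((len(coords), first, coords))
    raw.sort(key=lambda t: (-t[0], t[1]))
    lesions = []
    for cid, (count, _first, coords) in enumerate(raw, start=1):
        lesion = Lesion(
            component_id=cid,
            voxel_coords=coords,
            voxel_count=count,
            volume_mm3=count * voxel_vol,
            diameter_mm=0.0,
        )
        lesion.contour_pixels = lesion_contours(lesion)
        lesion.diameter_mm = lesion_diameter(lesion, labels.spacing, diameter_mode)
        lesions.append(lesion)
    return lesions


def lesion_diameter(
    lesion: Lesion,
    spacing: tuple[float, float, float],
    mode: DiameterMode = "equivalent_sphere",
) -> float:
    """Lesion diameter in mm.

    ``equivalent_sphere`` returns the diameter of the sphere matching the
    lesion's physical volume, ``2 * (3 V / (4 pi)) ** (1/3)``.
    ``max_inplane`` returns the largest physical distance between two
    contour pixels lying on the same slice (a RECIST-style long axis).
    """
    if lesion.voxel_count < 1:
        raise ValueError("lesion is empty")
    if mode == "equivalent_sphere":
        volume = lesion.voxel_count * float(np.prod(spacing))
        return float(2.0 * (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0))
    if mode == "max_inplane":
        contours = lesion.contour_pixels or lesion_contours(lesion)
        dr, dc = spacing[1], spacing[2]
        best = 0.0
        for pix in contours.values():
            pts = np.array(sorted(pix), dtype=float)
            if len(pts) == 1:
                continue
            phys = pts * np.array([dr, dc])
            diff = phys[:, None, :] - phys[None, :, :]
            best = max(best, float(np.sqrt((diff ** 2).sum(-1)).max()))
        return best
    raise ValueError(f"unknown diameter mode {mode!r}")


def lesion_contours(lesion: Lesion) -> dict[int, set[tuple[int, int]]]:
    """Per-slice contour pixels of a lesion.

    A contour pixel is a lesion pixel with at least one of its 4-neighbors
    (within the same slice) outside the lesion; pixels on the image border
    count the out-of-bounds side as background.
    """
    out: dict[int, set[tuple[int, int]]] = {}
    for s, pixels in lesion.slice_masks().items():
        contour = {
            (r, c)
            for (r, c) in pixels
            if any(
                (r + dr, c + dc) not in pixels
                for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1))
            )
        }
        out[s] = contour
    return out
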