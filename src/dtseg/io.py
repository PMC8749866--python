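"""NIfTI volume I/O and case-pairing records.

Volumes are stored as NIfTI (.nii/.nii.gz) with the voxel spacing encoded in
the header; masks are written as unsigned 8-bit, images and distance maps as
32-bit float.  Arrays keep the package's (z, y, x) index convention — the
affine is a plain diagonal spacing matrix, sufficient for round-tripping
spacing (no orientation metadata is modelled).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .volumes import BinaryMask, IntensityVolume, Spacing, as_spacing


def write_volume(data: np.ndarray, spacing, path) -> Path:
    """Write a 3D array with mm spacing; dtype chosen by content (mask→uint8)."""
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError(f"expected 3D data, got shape {data.shape}")
    spacing = as_spacing(spacing)
    is_mask = np.isin(np.unique(data), (0, 1)).all()
    out = data.astype(np.uint8 if is_mask else np.float32)
    affine = np.diag([*spacing, 1.0])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(out, affine), str(path))
    return path


def read_volume(path, *, as_mask: bool = False):
    """Read a NIfTI volume; returns :class:`BinaryMask` or
    :class:`IntensityVolume` with header spacing.

    Mask values {0, 255} are rescaled to {0, 1} with a warning; any other
    non-binary values raise.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if not as_mask:
        return IntensityVolume(data.astype(np.float64), spacing)
    values = np.unique(data)
    if np.isin(values, (0, 255)).all() and 255 in values:
        warnings.warn(f"{path}: rescaling mask values {{0,255}} to {{0,1}}")
        data = (data == 255).astype(np.uint8)
    elif not np.isin(values, (0, 1)).all():
        bad = [float(v) for v in values if v not in (0, 1)][:10]
        raise ValueError(f"{path}: non-binary label values {bad}")
    return BinaryMask(data.astype(np.uint8), spacing)


@dataclass
class CaseRecord:
    """Paths of one case's image/label (and optional distance map) on disk."""

    case_id: str
    image_path: Path
    label_path: Path
    dmap_path: Path | None = None
    spacing: Spacing = (0.625, 0.625, 0.625)

    @classmethod
    def load(cls, case_id, image_path, label_path, dmap_path=None) -> "CaseRecord":
        image = read_volume(image_path)
        label = read_volume(label_path, as_mask=True)
        if image.shape != label.shape:
            raise ValueError(
                f"{case_id}: image shape {image.shape} != label shape {label.shape}"
            )
        if any(abs(a - b) > 1e-4 for a, b in zip(image.spacing, label.spacing)):
            raise ValueError(
                f"{case_id}: image spacing {image.spacing} != label {label.spacing}"
            )
        return cls(case_id, Path(image_path), Path(label_path),
                   Path(dmap_path) if dmap_path else None, image.spacing)


def find_pairs(directory) -> list[CaseRecord]:
    """Pair ``*_img.nii.gz`` / ``*_lbl.nii.gz`` files in a directory."""
    directory = Path(directory)
    records = []
    for img_path in sorted(directory.glob("*_img.nii*")):
        stem = img_path.name.split("_img.nii")[0]
        lbl = list(directory.glob(f"{stem}_lbl.nii*"))
        if not lbl:
            raise FileNotFoundError(f"no label found for {img_path}")
        records.append(CaseRecord.load(stem, img_path, lbl[0]))
    return records
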