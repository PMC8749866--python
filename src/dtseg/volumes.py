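"""Core voxel-grid containers shared by every module.

All volumes are 3D numpy arrays in (z, y, x) index order with an isotropic or
anisotropic physical spacing in mm/voxel.  Masks are strictly binary {0, 1};
distance weight maps carry a ``method_tag`` that records which supervision-map
generator produced them and constrains their value range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

Spacing = tuple[float, float, float]

#: supervision-map provenance tags and their admissible value ranges
_MAP_TAGS = ("A", "B", "C", "raw")


def as_spacing(spacing) -> Spacing:
    """Validate and normalise a 3-component mm/voxel spacing."""
    s = tuple(float(v) for v in spacing)
    if len(s) != 3:
        raise ValueError(f"spacing must have 3 components, got {len(s)}")
    if any(v <= 0 for v in s):
        raise ValueError(f"spacing components must be positive, got {s}")
    return s  # type: ignore[return-value]


def _check_3d(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError(f"volume data must be 3D, got shape {data.shape}")
    return data


@dataclass
class Volume:
    """A 3D voxel grid with physical spacing (mm/voxel), (z, y, x) order."""

    data: np.ndarray
    spacing: Spacing = (0.625, 0.625, 0.625)

    def __post_init__(self) -> None:
        self.data = _check_3d(self.data)
        self.spacing = as_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class IntensityVolume(Volume):
    """Grayscale image volume (network input)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(np.float64, copy=False)


@dataclass
class BinaryMask(Volume):
    """Binary label/prediction volume; foreground voxels are 1, background 0."""

    def __post_init__(self) -> None:
        super().__post_init__()
        values = np.unique(self.data)
        if not np.isin(values, (0, 1)).all():
            bad = [v for v in values.tolist() if v not in (0, 1)][:10]
            raise ValueError(f"mask contains non-binary values {bad}")
        self.data = self.data.astype(np.uint8, copy=False)

    def foreground_count(self) -> int:
        return int(self.data.sum())


@dataclass
class DistanceWeightMap(Volume):
    """Distance-derived per-voxel field used to supervise / weight learning.

    ``method_tag`` 'A' and 'B' maps are continuous weights in [0, 1], largest
    at the region edge; 'C' is the binary edge label itself; 'raw' holds an
    unnormalised Euclidean distance field (voxel units).
    """

    method_tag: str = "raw"

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(np.float64, copy=False)
        if self.method_tag not in _MAP_TAGS:
            raise ValueError(
                f"method_tag must be one of {_MAP_TAGS}, got {self.method_tag!r}"
            )
        lo, hi = float(self.data.min(initial=0)), float(self.data.max(initial=0))
        if self.method_tag in ("A", "B"):
            if lo < -1e-9 or hi > 1 + 1e-9:
                raise ValueError(
                    f"method {self.method_tag} map must lie in [0,1], "
                    f"found range [{lo}, {hi}]"
                )
            np.clip(self.data, 0.0, 1.0, out=self.data)
        elif self.method_tag == "C":
            if not np.isin(np.unique(self.data), (0, 1)).all():
                raise ValueError("method C map must be binary")
        else:  # raw
            if lo < 0:
                raise ValueError(f"raw distance map must be >= 0, min {lo}")


def same_grid(a: Volume, b: Volume, *, atol: float = 1e-4) -> None:
    """Raise if two volumes disagree in shape or spacing (mm tolerance)."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if any(abs(x - y) > atol for x, y in zip(a.spacing, b.spacing)):
        raise ValueError(f"spacing mismatch: {a.spacing} vs {b.spacing}")
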