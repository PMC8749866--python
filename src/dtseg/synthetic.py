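"""Synthetic blob phantoms for end-to-end testing without real MRI data.

The generator emulates the statistical structure a left-atrium-style
segmentation task presents to the learner: a single connected, smooth,
blob-shaped foreground region (a union of overlapping ellipsoidal lobes)
inside a dark background, imaged with blurred edges (the partial-volume
effect) and additive Gaussian noise.  Every phantom is deterministic in its
seed, so training and evaluation runs are fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .volumes import BinaryMask, IntensityVolume, Spacing, as_spacing

#: voxels the label keeps clear of every volume face
MARGIN = 2

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


class PlacementError(ValueError):
    """Raised when a lobe cannot fit inside the margin along some axis."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic case.

    shape/spacing describe the voxel grid; ``n_lobes`` ellipsoids are merged
    into one connected blob; ``edge_blur_sigma`` (voxels) emulates the
    partial-volume effect; ``noise_sd`` is the additive Gaussian noise level
    in intensity units.
    """

    shape: tuple[int, int, int] = (48, 48, 24)
    spacing: Spacing = (0.625, 0.625, 0.625)
    n_lobes: int = 3
    edge_blur_sigma: float = 1.0
    noise_sd: float = 0.05
    fg_intensity: float = 1.0
    bg_intensity: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        shape = tuple(int(v) for v in self.shape)
        if len(shape) != 3 or any(v < 8 for v in shape):
            raise ValueError(f"shape components must be >= 8, got {shape}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", as_spacing(self.spacing))
        if self.n_lobes < 1:
            raise ValueError("n_lobes must be >= 1")
        if self.edge_blur_sigma < 0 or self.noise_sd < 0:
            raise ValueError("edge_blur_sigma and noise_sd must be >= 0")
        if self.fg_intensity == self.bg_intensity:
            raise ValueError("fg_intensity must differ from bg_intensity")


@dataclass
class PhantomCase:
    """A generated image/label pair plus the spec that produced it."""

    image: IntensityVolume
    label: BinaryMask
    spec: PhantomSpec

    def __post_init__(self) -> None:
        if self.image.shape != self.label.shape:
            raise ValueError("image and label shapes differ")
        if self.image.spacing != self.label.spacing:
            raise ValueError("image and label spacings differ")


def _ellipsoid(shape, center, axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes))
    return r2 <= 1.0


def _max_axis(center_i: float, dim: int) -> float:
    """Largest semi-axis keeping the ellipsoid MARGIN voxels off both faces."""
    return min(center_i - MARGIN, (dim - 1 - MARGIN) - center_i)


def make_phantom(spec: PhantomSpec) -> PhantomCase:
    """Generate one phantom case, deterministic in ``spec.seed``.

    The label is a union of ``n_lobes`` ellipsoids; every lobe after the
    first is centred at a point inside the first lobe, which guarantees a
    single face-connected foreground component.  The image is the label
    scaled to [bg, fg] intensity, Gaussian-blurred, plus Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape

    # principal lobe, near the volume centre
    center0 = np.array(shape, float) / 2.0 + rng.uniform(-1.5, 1.5, size=3)
    axes0 = np.empty(3)
    for i, dim in enumerate(shape):
        cap = _max_axis(center0[i], dim)
        if cap < 1.0:
            raise PlacementError(
                f"axis {i}: extent {dim} too small for margin {MARGIN}"
            )
        axes0[i] = min(rng.uniform(0.17, 0.30) * dim, cap)
    label = _ellipsoid(shape, center0, axes0)

    for _ in range(spec.n_lobes - 1):
        # centre drawn inside the principal lobe -> union stays connected;
        # if the lobe cannot fit inside the margin, retry with the offset
        # shrunk toward the principal centre
        u = rng.uniform(-0.7, 0.7, size=3)
        scales = rng.uniform(0.5, 0.9, size=3)
        for attempt in range(9):
            center = center0 + u * axes0
            caps = np.array([_max_axis(center[i], d) for i, d in enumerate(shape)])
            if caps.min() >= 1.0:
                break
            if attempt == 8:
                bad = int(caps.argmin())
                raise PlacementError(
                    f"axis {bad}: lobe at {center[bad]:.1f} cannot respect "
                    f"margin {MARGIN} in extent {shape[bad]}"
                )
            u *= 0.5
        axes = np.minimum(scales * axes0 + 1.0, caps)
        label |= _ellipsoid(shape, center, axes)

    label = label.astype(np.uint8)
    n_comp = ndimage.label(label, structure=_FACE_STRUCT)[1]
    if n_comp != 1:  # construction guarantees this; guard against regressions
        raise RuntimeError(f"phantom label has {n_comp} components, expected 1")

    image = spec.bg_intensity + (spec.fg_intensity - spec.bg_intensity) * label.astype(
        np.float64
    )
    if spec.edge_blur_sigma > 0:
        image = ndimage.gaussian_filter(image, sigma=spec.edge_blur_sigma)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=shape)

    return PhantomCase(
        image=IntensityVolume(image, spec.spacing),
        label=BinaryMask(label, spec.spacing),
        spec=spec,
    )


def make_dataset(
    n_cases: int, spec_template: PhantomSpec, seed: int
) -> list[PhantomCase]:
    """Generate ``n_cases`` phantoms with per-case seeds ``seed + index``."""
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    return [
        make_phantom(replace(spec_template, seed=seed + i)) for i in range(n_cases)
    ]
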