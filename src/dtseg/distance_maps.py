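"""Distance-transformation machinery: point classification, Euclidean
distance transform, grayscale conversion, and the three supervision-map
generators (Methods A, B, C).

A binary mask splits the voxel grid into target voxels (value 1) and
background voxels (value 0).  The Euclidean distance transform assigns each
target voxel its minimum distance to any background voxel.  Method A builds a
weight map that is exactly 1 on the region edge and decays with distance to
it on both sides; Method B builds an "error compensation" map by reflecting
the inside and outside distance fields about their own maxima and normalising
each side separately; Method C uses the binary edge itself as the
supervision target.

Distances are measured in voxel units (the intended imaging data are
isotropic, and min-max normalisation removes the scale anyway).  The
transform can run volumetrically (``"3d"``) or independently per axial slice
(``"2d_slicewise"``, slices taken along axis 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import BinaryMask, DistanceWeightMap

MODES = ("2d_slicewise", "3d")
CONNECTIVITIES = ("face_2d", "face_3d")


def _face_kernel(connectivity: str) -> np.ndarray:
    """Face-neighbour counting kernel: 4-neighbourhood in-slice, or 6 in 3D."""
    if connectivity == "face_2d":
        k = np.zeros((1, 3, 3))
        k[0] = [[0, 1, 0], [1, 0, 1], [0, 1, 0]]
    elif connectivity == "face_3d":
        k = np.zeros((3, 3, 3))
        k[0, 1, 1] = k[2, 1, 1] = 1
        k[1] = [[0, 1, 0], [1, 0, 1], [0, 1, 0]]
    else:
        raise ValueError(f"connectivity must be one of {CONNECTIVITIES}")
    return k


def _n_neighbors(connectivity: str) -> int:
    return 4 if connectivity == "face_2d" else 6


@dataclass
class PointClassification:
    """Disjoint split of the target voxels by their face neighbourhoods.

    internal: all face neighbours are target; isolated: all face neighbours
    are background; boundary: the remaining target voxels.  Voxels outside
    the volume count as background.
    """

    internal: np.ndarray
    isolated: np.ndarray
    boundary: np.ndarray


def classify_points(
    mask: BinaryMask, connectivity: str = "face_3d"
) -> PointClassification:
    """Split target voxels into internal / isolated / boundary points."""
    m = mask.data.astype(np.uint8)
    counts = ndimage.correlate(
        m.astype(np.int16), _face_kernel(connectivity), mode="constant", cval=0
    )
    target = m.astype(bool)
    internal = target & (counts == _n_neighbors(connectivity))
    isolated = target & (counts == 0)
    boundary = target & ~internal & ~isolated
    return PointClassification(
        internal=internal.astype(np.uint8),
        isolated=isolated.astype(np.uint8),
        boundary=boundary.astype(np.uint8),
    )


def extract_edge(mask: BinaryMask, connectivity: str = "face_3d") -> BinaryMask:
    """Target voxels with at least one background face neighbour.

    This is boundary ∪ isolated from :func:`classify_points` — an isolated
    voxel's whole extent is edge, so it is included.
    """
    cls = classify_points(mask, connectivity)
    return BinaryMask(cls.boundary | cls.isolated, mask.spacing)


class UndefinedDistanceError(ValueError):
    """A slice or volume has no background voxel, so distances are undefined."""


def euclidean_distance_transform(
    mask: BinaryMask, mode: str = "3d"
) -> DistanceWeightMap:
    """Minimum Euclidean distance (voxel units) of each target voxel to the
    background; 0 on background voxels.

    ``"2d_slicewise"`` applies the planar transform within each axis-0 slice
    independently; ``"3d"`` uses the volumetric transform.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    m = mask.data.astype(bool)
    if mode == "3d":
        if m.all():
            raise UndefinedDistanceError("volume has no background voxel")
        dist = ndimage.distance_transform_edt(m)
    else:
        dist = np.empty(m.shape, dtype=np.float64)
        for z in range(m.shape[0]):
            if m[z].all():
                raise UndefinedDistanceError(
                    f"slice {z} has no background voxel"
                )
            dist[z] = ndimage.distance_transform_edt(m[z])
    return DistanceWeightMap(dist, mask.spacing, method_tag="raw")


def to_grayscale(distances) -> np.ndarray:
    """Min-max rescale a set of distances to gray values in [0, 255].

    The value at the set minimum maps to 0 and at the maximum to 255.  A
    constant set carries no information and maps to all zeros.
    """
    d = np.asarray(distances, dtype=np.float64)
    if d.size == 0:
        raise ValueError("cannot convert an empty distance set to gray values")
    lo, hi = float(d.min()), float(d.max())
    if hi == lo:
        return np.zeros_like(d)
    return 255.0 * (d - lo) / (hi - lo)


def _minmax01(x: np.ndarray) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:  # constant field carries no weight information
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def _mode_connectivity(mode: str) -> str:
    return "face_2d" if mode == "2d_slicewise" else "face_3d"


def _distance_to_set(target_set: np.ndarray, mode: str) -> np.ndarray:
    """Distance of every voxel to the nearest voxel of ``target_set``.

    In slice-wise mode, slices containing no set voxel get +inf.
    """
    nonmember = ~target_set.astype(bool)
    if mode == "3d":
        return ndimage.distance_transform_edt(nonmember)
    dist = np.empty(nonmember.shape, dtype=np.float64)
    for z in range(nonmember.shape[0]):
        if nonmember[z].all():
            dist[z] = np.inf
        else:
            dist[z] = ndimage.distance_transform_edt(nonmember[z])
    return dist


def method_a(label: BinaryMask, mode: str = "3d") -> DistanceWeightMap:
    """Edge-anchored weight map: 1 on the edge, decaying to 0 at the voxel
    farthest from it.

    Pipeline: extract the label edge; reverse it; distance-transform the
    reversed image (every voxel gets its distance to the nearest edge voxel);
    min-max normalise to [0, 1]; subtract from 1.  Slices with no edge voxel
    (slice-wise mode only) carry no edge information and get weight 0.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    m = label.data.astype(bool)
    if not m.any() or m.all():
        raise ValueError("method A needs non-empty foreground and background")
    edge = extract_edge(label, _mode_connectivity(mode)).data
    dist = _distance_to_set(edge, mode)
    finite = np.isfinite(dist)
    out = np.zeros_like(dist)
    out[finite] = 1.0 - _minmax01(dist[finite])
    return DistanceWeightMap(out, label.spacing, method_tag="A")


def method_b(label: BinaryMask, mode: str = "3d") -> DistanceWeightMap:
    """Error-compensation weight map built from both sides of the edge.

    Foreground part: distance-transform the label, subtract each value from
    the generated maximum, take the absolute value, multiply by the label.
    Background part: the same steps on the reversed label.  Each part is
    min-max normalised to [0, 1] separately, then the two (disjointly
    supported) parts are added voxelwise.  The two sides are normalised by
    their own maxima, so intensities at equal distances inside and outside
    the edge are in general asymmetric.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    m = label.data.astype(np.float64)
    if not m.any() or m.all():
        raise ValueError("method B needs non-empty foreground and background")

    parts = []
    for side in (label, BinaryMask(1 - label.data, label.spacing)):
        d = euclidean_distance_transform(side, mode).data
        comp = np.abs(d.max() - d) * side.data
        parts.append(_minmax01(comp))
    return DistanceWeightMap(parts[0] + parts[1], label.spacing, method_tag="B")


def method_c(label: BinaryMask, mode: str = "3d") -> DistanceWeightMap:
    """Binary edge map used directly as the supervision target."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    edge = extract_edge(label, _mode_connectivity(mode))
    return DistanceWeightMap(
        edge.data.astype(np.float64), label.spacing, method_tag="C"
    )


GENERATORS = {"A": method_a, "B": method_b, "C": method_c}


def make_map(label: BinaryMask, method: str, mode: str = "3d") -> DistanceWeightMap:
    """Dispatch to Method A/B/C by name."""
    try:
        gen = GENERATORS[method.upper()]
    except KeyError:
        raise ValueError(f"method must be one of {sorted(GENERATORS)}") from None
    return gen(label, mode)
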