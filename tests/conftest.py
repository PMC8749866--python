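import numpy as np
import pytest

from dtseg.volumes import BinaryMask


# ---------------------------------------------------------------------------
# independent brute-force oracles (kept free of the library's EDT/surface code)
# ---------------------------------------------------------------------------

def _allpairs_min_dist(from_pts: np.ndarray, to_pts: np.ndarray) -> np.ndarray:
    """Exhaustive minimum distances between every pair of point sets."""
    if len(to_pts) == 0:
        return np.full(len(from_pts), np.inf)
    d2 = ((from_pts[:, None, :].astype(float) - to_pts[None, :, :]) ** 2).sum(-1)
    return np.sqrt(d2.min(axis=1))


def brute_force_edt(mask: np.ndarray, mode: str = "3d") -> np.ndarray:
    """All-pairs minimum Euclidean distance of target voxels to background."""
    mask = np.asarray(mask).astype(bool)
    out = np.zeros(mask.shape, dtype=float)
    if mode == "3d":
        tgt = np.argwhere(mask)
        bg = np.argwhere(~mask)
        if len(bg) == 0:
            raise ValueError("no background voxel")
        out[mask] = _allpairs_min_dist(tgt, bg)
        return out
    for z in range(mask.shape[0]):
        sl = mask[z]
        bg = np.argwhere(~sl)
        if len(bg) == 0:
            raise ValueError(f"no background in slice {z}")
        out[z][sl] = _allpairs_min_dist(np.argwhere(sl), bg)
    return out


def brute_force_distance_to_set(member: np.ndarray, mode: str = "3d") -> np.ndarray:
    """Distance of every voxel to the nearest voxel of ``member`` (inf if none)."""
    member = np.asarray(member).astype(bool)
    out = np.full(member.shape, np.inf)
    if mode == "3d":
        pts = np.argwhere(member)
        if len(pts) == 0:
            return out
        allv = np.argwhere(np.ones_like(member))
        return _allpairs_min_dist(allv, pts).reshape(member.shape)
    for z in range(member.shape[0]):
        pts = np.argwhere(member[z])
        if len(pts) == 0:
            continue
        allv = np.argwhere(np.ones_like(member[z]))
        out[z] = _allpairs_min_dist(allv, pts).reshape(member.shape[1:])
    return out


def brute_force_edge(mask: np.ndarray, connectivity: str = "face_3d") -> np.ndarray:
    """Target voxels with >= 1 background face neighbour, by explicit loops."""
    mask = np.asarray(mask).astype(bool)
    if connectivity == "face_2d":
        offsets = [(0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        offsets = [
            (1, 0, 0), (-1, 0, 0),
            (0, 1, 0), (0, -1, 0),
            (0, 0, 1), (0, 0, -1),
        ]
    edge = np.zeros(mask.shape, dtype=np.uint8)
    for v in np.argwhere(mask):
        for off in offsets:
            nb = v + np.array(off)
            if (nb < 0).any() or (nb >= mask.shape).any() or not mask[tuple(nb)]:
                edge[tuple(v)] = 1
                break
    return edge


@pytest.fixture
def random_mask():
    def _make(shape=(4, 9, 9), p=0.4, seed=0):
        rng = np.random.default_rng(seed)
        data = (rng.random(shape) < p).astype(np.uint8)
        # guarantee background everywhere the EDT preconditions need it
        data[:, 0, 0] = 0
        return BinaryMask(data, (1.0, 1.0, 1.0))

    return _make
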