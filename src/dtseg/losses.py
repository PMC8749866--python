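"""Training objectives: Dice, MAE, MSE, and the distance-weighted Distdice.

All four losses are written against a minimal array protocol (``+ - * /``,
``.sum()``, ``.mean()``, ``abs()``, ``.shape``) so the same code evaluates on
plain numpy arrays (analysis, tests) and on autodiff tensors (training);
there is a single implementation of each formula.

Dice Loss is the negated soft Dice coefficient, in [-1, 0).  Distdice keeps
Dice's denominator but weights the intersection voxelwise by a distance map
D, rewarding overlap most where D is large (near the region edge):

    L_distdice = -(2 * sum(y * p * D) + eps) / (sum(y) + sum(p) + eps)

With D ≡ 1 it reduces exactly to Dice Loss.  During two-stage training, D is
the first-stage distance decoder's output, detached from the gradient path.
"""

from __future__ import annotations

import numpy as np

from .volumes import Volume

EPS = 1e-5


def _unwrap(x):
    if isinstance(x, Volume):
        return x.data.astype(np.float64) if x.data.dtype != np.float64 else x.data
    return x


def _check_shapes(*arrays) -> None:
    shapes = [a.shape for a in arrays]
    if any(s != shapes[0] for s in shapes[1:]):
        raise ValueError(f"shape mismatch between loss inputs: {shapes}")


def dice_loss(pred, label, eps: float = EPS):
    """Negated soft Dice overlap; -1 at perfect overlap, ~0 when disjoint."""
    pred, label = _unwrap(pred), _unwrap(label)
    _check_shapes(pred, label)
    inter = (pred * label).sum()
    return -(2.0 * inter + eps) / (pred.sum() + label.sum() + eps)


def mae_loss(pred, target):
    """Mean absolute voxelwise difference, (1/N) Σ |y_i − p_i|."""
    pred, target = _unwrap(pred), _unwrap(target)
    _check_shapes(pred, target)
    return abs(pred - target).mean()


def mse_loss(pred, target):
    """Mean squared voxelwise difference, (1/N) Σ (y_i − p_i)²."""
    pred, target = _unwrap(pred), _unwrap(target)
    _check_shapes(pred, target)
    return ((pred - target) ** 2).mean()


def distdice_loss(pred, label, dmap, eps: float = EPS):
    """Dice loss with the intersection weighted voxelwise by ``dmap``.

    The denominator stays unweighted; ``dmap`` must be non-negative.
    """
    pred, label, dmap = _unwrap(pred), _unwrap(label), _unwrap(dmap)
    _check_shapes(pred, label, dmap)
    dvals = dmap if isinstance(dmap, np.ndarray) else np.asarray(dmap.data)
    if dvals.size and float(dvals.min()) < 0:
        raise ValueError("distance map passed to distdice_loss has negative values")
    inter = (pred * label * dmap).sum()
    return -(2.0 * inter + eps) / (pred.sum() + label.sum() + eps)


LOSSES = {"dice": dice_loss, "mae": mae_loss, "mse": mse_loss, "distdice": distdice_loss}
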