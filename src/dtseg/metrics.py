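"""Evaluation metrics: Dice similarity coefficient (%) and average symmetric
surface distance (mm).

The surface of a mask is its set of face-connected edge voxels.  ASSD takes,
for every surface voxel of the prediction, the minimum Euclidean distance (in
mm, scaled by voxel spacing) to the label surface, and vice versa, and
divides the summed distances by the total number of surface voxels on both
sides.  It is symmetric in its arguments by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .distance_maps import extract_edge
from .volumes import BinaryMask, same_grid


class EmptyMaskError(ValueError):
    """Surface distances are undefined for an empty mask."""


def dice_score(pred: BinaryMask, label: BinaryMask) -> float:
    """Dice similarity coefficient in percent; two empty masks agree (100)."""
    same_grid(pred, label)
    p, y = pred.data.astype(bool), label.data.astype(bool)
    denom = int(p.sum()) + int(y.sum())
    if denom == 0:
        return 100.0
    return 100.0 * 2.0 * int((p & y).sum()) / denom


def _surface_coords_mm(mask: BinaryMask) -> np.ndarray:
    surf = extract_edge(mask, "face_3d").data
    coords = np.argwhere(surf)
    return coords * np.asarray(mask.spacing)


def assd(pred: BinaryMask, label: BinaryMask) -> float:
    """Average symmetric surface distance in mm between two non-empty masks."""
    same_grid(pred, label)
    if not pred.data.any():
        raise EmptyMaskError("prediction mask is empty; surface undefined")
    if not label.data.any():
        raise EmptyMaskError("label mask is empty; surface undefined")
    sp = _surface_coords_mm(pred)
    sl = _surface_coords_mm(label)
    d_p_to_l = cKDTree(sl).query(sp)[0]
    d_l_to_p = cKDTree(sp).query(sl)[0]
    return float((d_p_to_l.sum() + d_l_to_p.sum()) / (len(sp) + len(sl)))


@dataclass
class EvalReport:
    """Per-case and aggregate Dice (%) / ASSD (mm).

    Cases whose ASSD is undefined (an empty mask on either side) are listed
    in ``excluded`` and dropped from both means with a warning.
    """

    per_case: list[tuple[str, float, float]] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)

    @property
    def mean_dice_percent(self) -> float:
        return float(np.mean([c[1] for c in self.per_case])) if self.per_case else float("nan")

    @property
    def mean_assd_mm(self) -> float:
        return float(np.mean([c[2] for c in self.per_case])) if self.per_case else float("nan")

    def to_dict(self) -> dict:
        return {
            "per_case": [
                {"case_id": cid, "dice_percent": d, "assd_mm": a}
                for cid, d, a in self.per_case
            ],
            "excluded": list(self.excluded),
            "mean_dice_percent": self.mean_dice_percent,
            "mean_assd_mm": self.mean_assd_mm,
        }

    def table(self) -> str:
        lines = [f"{'case':<16}{'Dice (%)':>10}{'Assd (mm)':>11}"]
        for cid, d, a in self.per_case:
            lines.append(f"{cid:<16}{d:>10.2f}{a:>11.3f}")
        lines.append(
            f"{'mean':<16}{self.mean_dice_percent:>10.2f}{self.mean_assd_mm:>11.3f}"
        )
        return "\n".join(lines)


def evaluate_pairs(
    pairs: list[tuple[str, BinaryMask, BinaryMask]]
) -> EvalReport:
    """Score (case_id, prediction, label) triples into an :class:`EvalReport`."""
    report = EvalReport()
    for case_id, pred, label in pairs:
        try:
            a = assd(pred, label)
        except EmptyMaskError as exc:
            warnings.warn(f"case {case_id} excluded from means: {exc}")
            report.excluded.append(case_id)
            continue
        report.per_case.append((case_id, dice_score(pred, label), a))
    return report
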