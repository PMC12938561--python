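"""Segmentation evaluation: Dice, HD95, recall and precision per region.

Conventions for degenerate inputs are declared explicitly: the Dice of two
empty masks is 1 (perfect agreement), HD95 is undefined (NaN) when either
mask is empty, recall is undefined for an empty reference and precision
for an empty prediction. Surface distances are computed between boundary
voxels (mask voxels with at least one non-mask 6-neighbor) in millimeters
using the voxel spacing; the 95th percentile uses linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from glioseg.labeling import compose_regions
from glioseg.volume_io import BinaryMask, LabelVolume


@dataclass
class RegionScores:
    """Per-region score bundle with the raw confusion counts."""

    region: str
    dsc: float
    hd95: float  # mm; NaN when undefined (an empty mask)
    recall: float
    precision: float
    tp: int
    fp: int
    fn: int


def _check(pred: BinaryMask, gt: BinaryMask) -> None:
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")


def dice(pred: BinaryMask, gt: BinaryMask) -> float:
    """Dice overlap 2|P∩G| / (|P| + |G|); two empty masks score 1."""
    _check(pred, gt)
    p, g = pred.data, gt.data
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(p, g).sum()) / denom


def _boundary_coords(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with at least one non-mask 6-neighbor."""
    if not mask.any():
        return np.empty((0, 3), dtype=np.int64)
    structure = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return np.argwhere(mask & ~interior)


def hd95(pred: BinaryMask, gt: BinaryMask,
         spacing=(1.0, 1.0, 1.0)) -> float:
    """95th-percentile symmetric surface distance in millimeters.

    The maximum of the two directed 95th-percentile boundary distances.
    Returns NaN when either mask is empty.
    """
    _check(pred, gt)
    if not pred.data.any() or not gt.data.any():
        return float("nan")
    sp = np.asarray(spacing, dtype=np.float64)
    bp = _boundary_coords(pred.data) * sp
    bg = _boundary_coords(gt.data) * sp
    d_pg, _ = cKDTree(bg).query(bp, k=1)
    d_gp, _ = cKDTree(bp).query(bg, k=1)
    return float(max(np.percentile(d_pg, 95), np.percentile(d_gp, 95)))


def recall_precision(pred: BinaryMask, gt: BinaryMask
                     ) -> tuple[float, float, int, int, int]:
    """Voxelwise (recall, precision, tp, fp, fn).

    Recall is NaN for an empty reference; precision is NaN for an empty
    prediction.
    """
    _check(pred, gt)
    p, g = pred.data, gt.data
    tp = int(np.logical_and(p, g).sum())
    fp = int(np.logical_and(p, ~g).sum())
    fn = int(np.logical_and(~p, g).sum())
    recall = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    precision = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    return recall, precision, tp, fp, fn


def score_region(pred: BinaryMask, gt: BinaryMask, region: str,
                 spacing=(1.0, 1.0, 1.0)) -> RegionScores:
    """All four metrics plus confusion counts for one region mask pair."""
    rec, prec, tp, fp, fn = recall_precision(pred, gt)
    return RegionScores(
        region=region,
        dsc=dice(pred, gt),
        hd95=hd95(pred, gt, spacing=spacing),
        recall=rec,
        precision=prec,
        tp=tp, fp=fp, fn=fn,
    )


def evaluate_case(pred_labels: LabelVolume, gt_labels: LabelVolume,
                  spacing=(1.0, 1.0, 1.0)) -> Dict[str, RegionScores]:
    """Score the WT/TC/ET composites of a predicted vs reference labeling."""
    if pred_labels.shape != gt_labels.shape:
        raise ValueError(
            f"shape mismatch: {pred_labels.shape} vs {gt_labels.shape}")
    pred_regions = compose_regions(pred_labels)
    gt_regions = compose_regions(gt_labels)
    return {
        region: score_region(pred_regions[region], gt_regions[region],
                             region, spacing=spacing)
        for region in ("WT", "TC", "ET")
    }
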