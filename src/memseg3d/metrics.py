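"""Instance-segmentation evaluation: per-cell JI/DSC, ARE, and VOI.

Per-cell overlap ratios (Jaccard index and Dice similarity coefficient) are
computed after matching each ground-truth cell to the predicted instance
with maximal voxel intersection. Summary accuracies are the averages
(Avg JI / Avg DSC, "overall accuracy") and the fraction of cells whose JI
(or DSC) exceeds 0.7 or 0.5 ("cell count accuracy"; strictly greater).
Partition-level metrics are the adapted Rand error (1 minus the
pair-counting F-score between the two partitions) and the variation of
information split into conditional entropies: split = H(pred | gt) measures
over-segmentation, merge = H(gt | pred) under-segmentation, in bits.

Background (label 0 in the ground truth) is excluded from the partition
metrics; all metrics are invariant to label permutations of either input.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .volume_io import LabelVolume

__all__ = [
    "MatchRow",
    "CellMatchTable",
    "EvaluationReport",
    "match_instances",
    "jaccard",
    "dsc",
    "adapted_rand_error",
    "variation_of_information",
    "evaluate",
]


@dataclasses.dataclass
class MatchRow:
    gt_id: int
    pred_id: Optional[int]  # None when no predicted instance overlaps the cell
    intersection: int
    ji: float
    dsc: float


@dataclasses.dataclass
class CellMatchTable:
    rows: list[MatchRow]

    def __iter__(self):
        return iter(self.rows)

    def __len__(self):
        return len(self.rows)


@dataclasses.dataclass
class EvaluationReport:
    """All summary metrics of one prediction against ground truth."""

    avg_ji: float
    avg_dsc: float
    frac_ji_gt_70: float
    frac_dsc_gt_70: float
    frac_ji_gt_50: float
    frac_dsc_gt_50: float
    are: float
    voi_split: float
    voi_merge: float
    n_gt_cells: int
    n_pred_instances: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _arrays(pred, gt) -> tuple[np.ndarray, np.ndarray]:
    p = pred.labels if isinstance(pred, LabelVolume) else np.asarray(pred)
    g = gt.labels if isinstance(gt, LabelVolume) else np.asarray(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    return p, g


def jaccard(seg: np.ndarray, gt: np.ndarray) -> float:
    """|seg ∩ gt| / |seg ∪ gt| over boolean voxel sets; 1 if both empty."""
    seg = np.asarray(seg).astype(bool)
    gt = np.asarray(gt).astype(bool)
    union = np.logical_or(seg, gt).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(seg, gt).sum() / union)


def dsc(seg: np.ndarray, gt: np.ndarray) -> float:
    """2|seg ∩ gt| / (|seg| + |gt|) over boolean voxel sets; 1 if both empty."""
    seg = np.asarray(seg).astype(bool)
    gt = np.asarray(gt).astype(bool)
    total = seg.sum() + gt.sum()
    if total == 0:
        return 1.0
    return float(2.0 * np.logical_and(seg, gt).sum() / total)


def _contingency(pred: np.ndarray, gt: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sparse contingency counts n_ij over gt-foreground voxels."""
    sel = gt > 0
    g = gt[sel].astype(np.int64)
    p = pred[sel].astype(np.int64)
    if g.size == 0:
        raise ValueError("ground truth contains no foreground cells")
    code = g * (p.max() + 1) + p
    uniq, counts = np.unique(code, return_counts=True)
    gi = uniq // (p.max() + 1)
    pi = uniq % (p.max() + 1)
    return gi, pi, counts


def match_instances(pred, gt) -> CellMatchTable:
    """Match every ground-truth cell to its maximal-overlap predicted instance.

    Ties go to the smaller predicted id; cells overlapped by no predicted
    instance (only background) get JI = DSC = 0. JI/DSC are computed over
    the full voxel sets of the matched pair, so they are invariant to
    relabeling of either volume.
    """
    p, g = _arrays(pred, gt)
    gi, pi, counts = _contingency(p, g)
    gt_ids, gt_sizes = np.unique(g[g > 0], return_counts=True)
    gt_size = dict(zip(gt_ids.tolist(), gt_sizes.tolist()))
    pred_ids, pred_sizes = np.unique(p[p > 0], return_counts=True)
    pred_size = dict(zip(pred_ids.tolist(), pred_sizes.tolist()))

    best: dict[int, tuple[int, int]] = {}  # gt_id -> (intersection, pred_id)
    for a, b, c in zip(gi.tolist(), pi.tolist(), counts.tolist()):
        if b == 0:
            continue
        cur = best.get(a)
        if cur is None or (c, -b) > (cur[0], -cur[1]):
            best[a] = (int(c), int(b))
    rows = []
    for gt_id in gt_ids.tolist():
        if gt_id in best:
            inter, pred_id = best[gt_id]
            union = gt_size[gt_id] + pred_size[pred_id] - inter
            rows.append(
                MatchRow(
                    gt_id=gt_id,
                    pred_id=pred_id,
                    intersection=inter,
                    ji=inter / union,
                    dsc=2.0 * inter / (gt_size[gt_id] + pred_size[pred_id]),
                )
            )
        else:
            rows.append(MatchRow(gt_id=gt_id, pred_id=None, intersection=0, ji=0.0, dsc=0.0))
    return CellMatchTable(rows)


def adapted_rand_error(pred, gt) -> tuple[float, float, float]:
    """Adapted Rand error: 1 - F-score of pair-counting precision/recall.

    Computed from the contingency table restricted to ground-truth
    foreground voxels (background excluded from pair counting). Returns
    ``(are, precision, recall)``; identical partitions give exactly 0.
    """
    p, g = _arrays(pred, gt)
    gi, pi, counts = _contingency(p, g)
    n = counts.astype(np.float64)
    total = n.sum()
    a = {}
    b = {}
    for x, c in zip(pi.tolist(), counts.tolist()):
        a[x] = a.get(x, 0) + c
    for x, c in zip(gi.tolist(), counts.tolist()):
        b[x] = b.get(x, 0) + c
    # distinct-pair counting: subtract the N self-pairs from each quadratic sum
    tp = float((n**2).sum()) - total
    pred_pairs = float(sum(v**2 for v in a.values())) - total
    gt_pairs = float(sum(v**2 for v in b.values())) - total
    precision = tp / pred_pairs if pred_pairs > 0 else 1.0
    recall = tp / gt_pairs if gt_pairs > 0 else 1.0
    if precision + recall == 0.0:
        return 1.0, precision, recall
    f = 2.0 * precision * recall / (precision + recall)
    return 1.0 - f, precision, recall


def variation_of_information(pred, gt) -> tuple[float, float]:
    """VOI conditional entropies in bits over gt-foreground voxels.

    Returns ``(voi_split, voi_merge)`` = (H(pred|gt), H(gt|pred)): split
    charges over-segmentation (one gt cell spread over several predicted
    instances), merge charges under-segmentation. Their sum is
    2 H(joint) - H(pred) - H(gt).
    """
    p, g = _arrays(pred, gt)
    gi, pi, counts = _contingency(p, g)
    n = counts.astype(np.float64)
    total = n.sum()
    pij = n / total
    h_joint = -np.sum(pij * np.log2(pij))

    def marg_entropy(ids):
        m: dict[int, float] = {}
        for x, c in zip(ids.tolist(), n.tolist()):
            m[x] = m.get(x, 0.0) + c
        q = np.array(list(m.values())) / total
        return -np.sum(q * np.log2(q))

    h_gt = marg_entropy(gi)
    h_pred = marg_entropy(pi)
    return float(h_joint - h_gt), float(h_joint - h_pred)


def evaluate(pred, gt) -> EvaluationReport:
    """Aggregate the per-cell match table and partition metrics."""
    p, g = _arrays(pred, gt)
    table = match_instances(p, g)
    ji = np.array([r.ji for r in table.rows])
    dc = np.array([r.dsc for r in table.rows])
    are, _, _ = adapted_rand_error(p, g)
    voi_split, voi_merge = variation_of_information(p, g)
    return EvaluationReport(
        avg_ji=float(ji.mean()),
        avg_dsc=float(dc.mean()),
        frac_ji_gt_70=float((ji > 0.7).mean()),
        frac_dsc_gt_70=float((dc > 0.7).mean()),
        frac_ji_gt_50=float((ji > 0.5).mean()),
        frac_dsc_gt_50=float((dc > 0.5).mean()),
        are=float(are),
        voi_split=voi_split,
        voi_merge=voi_merge,
        n_gt_cells=len(table),
        n_pred_instances=int(len(np.unique(p[p > 0]))),
    )
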