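"""Instance-segmentation evaluation against ground truth.

One-to-one matching of predicted to true labels by intersection-over-union
using the Hungarian assignment, the standard protocol for scoring instance
segmentations against a reference labelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.sparse import coo_matrix

from .volume import LabelVolume

__all__ = ["MatchResult", "match_labels"]


@dataclass
class MatchResult:
    pairs: list[tuple[int, int, float]]  # (true label, predicted label, IoU)
    n_true: int
    n_pred: int

    def matched(self, min_iou: float = 0.7) -> list[tuple[int, int, float]]:
        return [p for p in self.pairs if p[2] >= min_iou]

    def recovery(self, min_iou: float = 0.7) -> float:
        """Fraction of true labels matched one-to-one at ``min_iou``."""
        if self.n_true == 0:
            return float("nan")
        return len(self.matched(min_iou)) / self.n_true

    def mapping(self, min_iou: float = 0.5) -> dict[int, int]:
        """true label -> predicted label for pairs above ``min_iou``."""
        return {t: p for t, p, iou in self.pairs if iou >= min_iou}


def match_labels(truth: LabelVolume, pred: LabelVolume) -> MatchResult:
    """Hungarian one-to-one matching of true and predicted labels by IoU."""
    if truth.shape != pred.shape:
        raise ValueError("label volumes must share the grid")
    t = truth.labels.ravel()
    p = pred.labels.ravel()
    true_ids = truth.label_ids()
    pred_ids = pred.label_ids()
    if true_ids.size == 0 or pred_ids.size == 0:
        return MatchResult([], int(true_ids.size), int(pred_ids.size))
    both = (t > 0) & (p > 0)
    rows_idx = np.searchsorted(true_ids, t[both])
    cols_idx = np.searchsorted(pred_ids, p[both])
    inter = coo_matrix(
        (np.ones(rows_idx.size), (rows_idx, cols_idx)),
        shape=(true_ids.size, pred_ids.size),
    ).toarray()
    t_sizes = np.bincount(t)[true_ids]
    p_sizes = np.bincount(p)[pred_ids]
    union = t_sizes[:, None] + p_sizes[None, :] - inter
    iou = np.where(union > 0, inter / union, 0.0)
    rows, cols = linear_sum_assignment(-iou)
    pairs = [
        (int(true_ids[r]), int(pred_ids[c]), float(iou[r, c]))
        for r, c in zip(rows, cols)
        if iou[r, c] > 0
    ]
    return MatchResult(pairs, int(true_ids.size), int(pred_ids.size))
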