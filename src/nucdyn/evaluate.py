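"""Evaluation of segmentation and tracking against ground truth."""

from __future__ import annotations

import numpy as np

__all__ = ["match_labels", "segmentation_scores", "link_accuracy"]


def _overlap_table(truth: np.ndarray, pred: np.ndarray):
    both = (truth > 0) & (pred > 0)
    pairs = np.stack([truth[both], pred[both]], axis=1)
    if pairs.size == 0:
        return np.zeros((0, 2), int), np.zeros(0, int)
    return np.unique(pairs, axis=0, return_counts=True)


def match_labels(truth: np.ndarray, pred: np.ndarray, iou_threshold: float = 0.5
                 ) -> dict[int, tuple[int, float]]:
    """Greedy one-to-one matching of predicted to true labels by IoU.

    Returns ``{true_label: (pred_label, iou)}`` for matches at or above
    the threshold.
    """
    uniq, counts = _overlap_table(truth, pred)
    size_t = {int(l): int(np.count_nonzero(truth == l)) for l in np.unique(truth) if l > 0}
    size_p = {int(l): int(np.count_nonzero(pred == l)) for l in np.unique(pred) if l > 0}
    cands = []
    for (lt, lp), ov in zip(uniq, counts):
        lt, lp, ov = int(lt), int(lp), int(ov)
        iou = ov / (size_t[lt] + size_p[lp] - ov)
        if iou >= iou_threshold:
            cands.append((iou, lt, lp))
    cands.sort(reverse=True)
    matched: dict[int, tuple[int, float]] = {}
    used_pred: set[int] = set()
    for iou, lt, lp in cands:
        if lt in matched or lp in used_pred:
            continue
        matched[lt] = (lp, iou)
        used_pred.add(lp)
    return matched


def segmentation_scores(truth: np.ndarray, pred: np.ndarray,
                        iou_threshold: float = 0.5) -> dict[str, float]:
    """Detection precision/recall and mean IoU of matched nuclei."""
    matches = match_labels(truth, pred, iou_threshold)
    n_truth = len([l for l in np.unique(truth) if l > 0])
    n_pred = len([l for l in np.unique(pred) if l > 0])
    tp = len(matches)
    mean_iou = float(np.mean([iou for _, iou in matches.values()])) if matches else 0.0
    return {
        "precision": tp / n_pred if n_pred else 0.0,
        "recall": tp / n_truth if n_truth else 0.0,
        "mean_iou": mean_iou,
        "n_truth": n_truth,
        "n_pred": n_pred,
    }


def link_accuracy(truth_labels: np.ndarray, tracked_labels: np.ndarray,
                  iou_threshold: float = 0.5) -> dict[str, float]:
    """Fraction of frame-to-frame links agreeing with ground-truth identity.

    For each consecutive frame pair, a true nucleus present (and matched)
    in both frames contributes one link; the link is correct when the
    tracked label it maps to is the same in both frames.
    """
    n_links = n_correct = 0
    for t in range(truth_labels.shape[0] - 1):
        m0 = match_labels(truth_labels[t], tracked_labels[t], iou_threshold)
        m1 = match_labels(truth_labels[t + 1], tracked_labels[t + 1], iou_threshold)
        for true_id, (pred0, _) in m0.items():
            if true_id in m1:
                n_links += 1
                if m1[true_id][0] == pred0:
                    n_correct += 1
    return {
        "n_links": n_links,
        "n_correct": n_correct,
        "accuracy": n_correct / n_links if n_links else float("nan"),
    }
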