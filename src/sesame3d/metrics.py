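"""Evaluation metrics for organ segmentation and trait agreement.

Semantic segmentation is scored with overall accuracy (OA) and mean
intersection-over-union (mIoU) from a confusion matrix; leaf instance
segmentation with per-leaf precision/recall/F1 after greedy overlap
matching of predicted clusters to ground-truth leaves; trait agreement
with the coefficient of determination R^2 and RMSE.
"""

from __future__ import annotations

import numpy as np


def confusion(true_labels, pred_labels, m: int) -> np.ndarray:
    """m x m confusion matrix; rows = true class, columns = predicted."""
    t = np.asarray(true_labels, dtype=np.int64).reshape(-1)
    p = np.asarray(pred_labels, dtype=np.int64).reshape(-1)
    if t.shape != p.shape:
        raise ValueError("true and predicted label arrays differ in length")
    if t.size and (t.min() < 0 or t.max() >= m or p.min() < 0 or p.max() >= m):
        raise ValueError(f"labels must lie in [0, {m})")
    cm = np.zeros((m, m), dtype=np.int64)
    np.add.at(cm, (t, p), 1)
    return cm


def overall_accuracy(cm: np.ndarray) -> float:
    """OA = correctly labelled points / all points (trace over total)."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm) / total)


def miou(cm: np.ndarray) -> float:
    """Mean per-class IoU = mean of TP / (TP + FP + FN).

    Classes absent from both truth and prediction (TP+FP+FN = 0) are
    excluded from the mean rather than counted as 0/0.
    """
    cm = np.asarray(cm, dtype=np.float64)
    tp = np.diag(cm)
    denom = cm.sum(axis=0) + cm.sum(axis=1) - tp
    valid = denom > 0
    if not valid.any():
        raise ValueError("no class has any support; mIoU undefined")
    return float((tp[valid] / denom[valid]).mean())


def match_instances(
    true_instances, pred_instances
) -> tuple[dict[int, int], list[int], list[int]]:
    """Greedy one-to-one matching of predicted clusters to ground-truth leaves.

    Pairs are consumed in order of descending point overlap; each ground-truth
    leaf and each predicted cluster is used at most once. Noise labels (-1)
    never participate. Returns ``(pred_to_true, unmatched_true, unmatched_pred)``.
    """
    t = np.asarray(true_instances, dtype=np.int64).reshape(-1)
    p = np.asarray(pred_instances, dtype=np.int64).reshape(-1)
    if t.shape != p.shape:
        raise ValueError("instance arrays differ in length")
    overlaps = {}
    valid = (t >= 0) & (p >= 0)
    for ti, pi in zip(t[valid], p[valid]):
        overlaps[(int(pi), int(ti))] = overlaps.get((int(pi), int(ti)), 0) + 1
    # sort by overlap desc, then ids for determinism
    pairs = sorted(overlaps.items(), key=lambda kv: (-kv[1], kv[0]))
    pred_to_true: dict[int, int] = {}
    used_true: set[int] = set()
    for (pi, ti), _ in pairs:
        if pi in pred_to_true or ti in used_true:
            continue
        pred_to_true[pi] = ti
        used_true.add(ti)
    unmatched_true = sorted(set(int(v) for v in t[t >= 0]) - used_true)
    unmatched_pred = sorted(set(int(v) for v in p[p >= 0]) - set(pred_to_true))
    return pred_to_true, unmatched_true, unmatched_pred


def instance_prf1(true_instances, pred_instances) -> dict:
    """Per-leaf and macro precision / recall / F1 for instance segmentation.

    For a ground-truth leaf A matched to predicted cluster C: TP = points of
    A predicted as C, FP = points of C not belonging to A, FN = points of A
    not predicted as C (noise predictions therefore count as FN). Unmatched
    ground-truth leaves contribute P = R = F1 = 0; F1 = 0 when P + R = 0.
    """
    t = np.asarray(true_instances, dtype=np.int64).reshape(-1)
    p = np.asarray(pred_instances, dtype=np.int64).reshape(-1)
    true_ids = sorted(set(int(v) for v in t[t >= 0]))
    if not true_ids:
        raise ValueError("no ground-truth leaves")
    pred_to_true, _, _ = match_instances(t, p)
    true_to_pred = {ti: pi for pi, ti in pred_to_true.items()}
    per_leaf = {}
    for ti in true_ids:
        if ti not in true_to_pred:
            per_leaf[ti] = {"precision": 0.0, "recall": 0.0, "f1": 0.0}
            continue
        pi = true_to_pred[ti]
        tp = int(((t == ti) & (p == pi)).sum())
        fp = int(((t != ti) & (p == pi)).sum())
        fn = int(((t == ti) & (p != pi)).sum())
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_leaf[ti] = {"precision": prec, "recall": rec, "f1": f1}
    macro = {
        key: float(np.mean([v[key] for v in per_leaf.values()]))
        for key in ("precision", "recall", "f1")
    }
    return {"per_leaf": per_leaf, "macro": macro}


def r_squared(actual, predicted) -> float:
    """Coefficient of determination R^2 = 1 - SS_res / SS_tot."""
    y = np.asarray(actual, dtype=np.float64).reshape(-1)
    yhat = np.asarray(predicted, dtype=np.float64).reshape(-1)
    if y.shape != yhat.shape:
        raise ValueError("vectors differ in length")
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("actual values are constant; R^2 undefined")
    ss_res = float(((y - yhat) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def regression_r_squared(actual, predicted) -> float:
    """R^2 of the fitted linear regression predicted ~ actual.

    Equals the squared Pearson correlation; this is the statistic a
    fitted-line agreement plot reports, insensitive to calibration bias
    or slope, unlike the direct :func:`r_squared`.
    """
    y = np.asarray(actual, dtype=np.float64).reshape(-1)
    yhat = np.asarray(predicted, dtype=np.float64).reshape(-1)
    if y.size < 2 or y.std() == 0 or yhat.std() == 0:
        raise ValueError("degenerate input for regression R^2")
    return float(np.corrcoef(y, yhat)[0, 1] ** 2)


def rmse(actual, predicted) -> float:
    """Root mean squared error."""
    y = np.asarray(actual, dtype=np.float64).reshape(-1)
    yhat = np.asarray(predicted, dtype=np.float64).reshape(-1)
    if y.shape != yhat.shape:
        raise ValueError("vectors differ in length")
    if y.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(((y - yhat) ** 2).mean()))
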