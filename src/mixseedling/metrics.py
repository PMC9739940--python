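"""Evaluation metrics: per-class accuracy/IoU/mIoU from one-vs-rest confusion
tables, instance-level mean precision/recall at IoU > 0.5, F-score@1% for
completion, and the R^2 / MSE / RMSE correlation summary used by the
phenotyping study."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ConfusionTable",
    "semantic_scores",
    "instance_prec_rec",
    "fscore_at",
    "r2_mse",
]


@dataclass
class ConfusionTable:
    """Per-class one-vs-rest counts over a fixed point set."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @classmethod
    def from_labels(cls, pred: np.ndarray, true: np.ndarray, n_classes: int) -> "ConfusionTable":
        pred = np.asarray(pred, dtype=np.int64)
        true = np.asarray(true, dtype=np.int64)
        tp = np.empty(n_classes, dtype=np.int64)
        fp = np.empty(n_classes, dtype=np.int64)
        fn = np.empty(n_classes, dtype=np.int64)
        tn = np.empty(n_classes, dtype=np.int64)
        for i in range(n_classes):
            p = pred == i
            t = true == i
            tp[i] = int((p & t).sum())
            fp[i] = int((p & ~t).sum())
            fn[i] = int((~p & t).sum())
            tn[i] = int((~p & ~t).sum())
        return cls(tp, fp, fn, tn)


def semantic_scores(
    pred_labels: np.ndarray, true_labels: np.ndarray, n_classes: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-class accuracy, per-class IoU and their mean (mIoU).

    ``ACC_i = (TP_i + TN_i) / (TP_i + FP_i + FN_i + TN_i)``,
    ``IoU_i = TP_i / (TP_i + FP_i + FN_i)``.  Points labeled -1 in the truth
    are excluded.  A class absent from both prediction and truth has undefined
    IoU: it is reported as NaN and excluded from the mean, with a warning.
    """
    pred = np.asarray(pred_labels, dtype=np.int64)
    true = np.asarray(true_labels, dtype=np.int64)
    if pred.shape != true.shape:
        raise ValueError("prediction and truth must have the same length")
    valid = true >= 0
    pred, true = pred[valid], true[valid]
    table = ConfusionTable.from_labels(pred, true, n_classes)
    total = table.tp + table.fp + table.fn + table.tn
    acc = (table.tp + table.tn) / total
    denom = table.tp + table.fp + table.fn
    iou = np.full(n_classes, np.nan)
    present = denom > 0
    iou[present] = table.tp[present] / denom[present]
    if not present.all():
        warnings.warn(
            f"classes {np.flatnonzero(~present).tolist()} absent from both "
            "prediction and truth; excluded from mIoU",
            stacklevel=2,
        )
    miou = float(np.nanmean(iou))
    return acc, iou, miou


def _instances_by_class(inst: np.ndarray, sem_of_instance: dict[int, int]) -> dict[int, list[np.ndarray]]:
    """Group instance point-masks by their semantic class."""
    out: dict[int, list[np.ndarray]] = {}
    for i in np.unique(inst[inst >= 0]):
        cls = sem_of_instance[int(i)]
        out.setdefault(cls, []).append(inst == i)
    return out


def instance_prec_rec(
    pred_instances: np.ndarray,
    gt_instances: np.ndarray,
    pred_sem_of_instance: dict[int, int],
    gt_sem_of_instance: dict[int, int],
    classes: tuple[int, ...] = (0, 1),
) -> tuple[float, float]:
    """Instance-level mean precision/recall at point-set IoU > 0.5.

    A predicted instance is a true positive when its best IoU against a
    not-yet-matched ground-truth instance of the same semantic class exceeds
    0.5 (greedy matching in descending IoU order).  Precision averages
    TP/|predicted| over classes, recall TP/|ground truth|; a class with no
    predicted instances contributes precision 0, and with no ground-truth
    instances recall 0.
    """
    pred_instances = np.asarray(pred_instances, dtype=np.int64)
    gt_instances = np.asarray(gt_instances, dtype=np.int64)
    if pred_instances.shape != gt_instances.shape:
        raise ValueError("instance maps must cover the same point set")
    pred_by_cls = _instances_by_class(pred_instances, pred_sem_of_instance)
    gt_by_cls = _instances_by_class(gt_instances, gt_sem_of_instance)
    precs, recs = [], []
    for cls in classes:
        preds = pred_by_cls.get(cls, [])
        gts = gt_by_cls.get(cls, [])
        if preds and gts:
            iou = np.zeros((len(preds), len(gts)))
            for a, pm in enumerate(preds):
                for b, gm in enumerate(gts):
                    inter = (pm & gm).sum()
                    union = (pm | gm).sum()
                    iou[a, b] = inter / union if union else 0.0
            matched_gt = np.zeros(len(gts), dtype=bool)
            tp = 0
            for a, b in sorted(
                ((a, b) for a in range(len(preds)) for b in range(len(gts))),
                key=lambda ab: -iou[ab],
            ):
                if iou[a, b] <= 0.5:
                    break
                if not matched_gt[b]:
                    matched_gt[b] = True
                    tp += 1
        else:
            tp = 0
        precs.append(tp / len(preds) if preds else 0.0)
        recs.append(tp / len(gts) if gts else 0.0)
    return float(np.mean(precs)), float(np.mean(recs))


def fscore_at(s_pred: np.ndarray, s_gt: np.ndarray, tau: float = 0.01) -> float:
    """F-score at distance threshold ``tau`` (1% of the normalized extent).

    Precision: fraction of predicted points within ``tau`` of some ground
    truth point; recall: vice versa; F = 2PR/(P+R), 0 when P + R = 0.
    """
    s_pred = np.asarray(s_pred, dtype=np.float64)
    s_gt = np.asarray(s_gt, dtype=np.float64)
    if len(s_pred) == 0 or len(s_gt) == 0:
        raise ValueError("F-score of an empty cloud is undefined")
    d_pred, _ = cKDTree(s_gt).query(s_pred)
    d_gt, _ = cKDTree(s_pred).query(s_gt)
    precision = float((d_pred <= tau).mean())
    recall = float((d_gt <= tau).mean())
    if precision + recall == 0.0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def r2_mse(measured: np.ndarray, predicted: np.ndarray) -> tuple[float, float, float]:
    """Coefficient of determination and (root) mean squared error.

    ``R^2 = 1 - sum (v - v')^2 / sum (v - vbar)^2`` with ``v`` the manual
    measurements and ``v'`` the predictions; ``MSE = sum (v - v')^2 / m`` and
    ``RMSE = sqrt(MSE)`` are both returned since reports in this field label
    either one.  Returns ``(R2, MSE, RMSE)``.
    """
    v = np.asarray(measured, dtype=np.float64)
    vp = np.asarray(predicted, dtype=np.float64)
    if v.shape != vp.shape or v.ndim != 1:
        raise ValueError("measured and predicted must be equal-length 1-D arrays")
    if len(v) < 2:
        raise ValueError("need at least two paired values")
    ss_res = float(((v - vp) ** 2).sum())
    ss_tot = float(((v - v.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("measured values have zero variance; R^2 undefined")
    r2 = 1.0 - ss_res / ss_tot
    mse = ss_res / len(v)
    return r2, mse, float(np.sqrt(mse))
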