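"""Segmentation evaluation metrics.

Semantic (point-level, two classes: branch = 0, leaf = 1):
    per-class precision = TP / (TP + FP), recall = TP / (TP + FN),
    F1 = harmonic mean, IoU = TP / (TP + FP + FN), plus the unweighted
    two-class means.

Instance (leaf instances as point-index sets):
    mCov — for each ground-truth instance, the best point-level IoU over
    all predicted instances, averaged over ground-truth instances;
    instance precision/recall — predicted and truth instances are matched
    one-to-one greedily by descending IoU, T counts matched pairs with
    IoU strictly greater than the threshold (0.5), precision = T / #pred,
    recall = T / #truth.

Zero denominators are reported as 0.0 with an ``undefined`` flag rather
than NaN, so reports aggregate safely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np

__all__ = [
    "SemanticReport",
    "InstanceReport",
    "semantic_metrics",
    "instance_iou",
    "mcov",
    "instance_pr",
]

CLASS_NAMES = {0: "branch", 1: "leaf"}


@dataclass
class SemanticReport:
    """Per-class counts and rates, plus two-class means."""

    per_class: Dict[str, Dict[str, float]]
    mean_precision: float
    mean_recall: float
    mean_f1: float
    mean_iou: float
    undefined: List[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "per_class": self.per_class,
            "mean_precision": self.mean_precision,
            "mean_recall": self.mean_recall,
            "mean_f1": self.mean_f1,
            "mean_iou": self.mean_iou,
            "undefined": self.undefined,
        }


@dataclass
class InstanceReport:
    """Instance-level matching summary at a fixed IoU threshold."""

    T: int
    P_pred: int
    G: int
    precision_ins: float
    recall_ins: float
    mcov: float
    undefined: List[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "T": self.T,
            "P_pred": self.P_pred,
            "G": self.G,
            "precision_ins": self.precision_ins,
            "recall_ins": self.recall_ins,
            "mcov": self.mcov,
            "undefined": self.undefined,
        }


def _safe_div(num: float, den: float, flag: str, undefined: List[str]) -> float:
    if den == 0:
        undefined.append(flag)
        return 0.0
    return num / den


def semantic_metrics(true_labels: np.ndarray, pred_labels: np.ndarray) -> SemanticReport:
    """Point-level precision/recall/F1/IoU per class and their means."""
    t = np.asarray(true_labels)
    p = np.asarray(pred_labels)
    if t.size == 0:
        raise ValueError("empty label vectors")
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    if not (np.isin(t, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels must be binary (0 = branch, 1 = leaf)")
    undefined: List[str] = []
    per_class: Dict[str, Dict[str, float]] = {}
    precs, recs, f1s, ious = [], [], [], []
    for c in (0, 1):
        name = CLASS_NAMES[c]
        tp = int(np.sum((t == c) & (p == c)))
        fp = int(np.sum((t != c) & (p == c)))
        fn = int(np.sum((t == c) & (p != c)))
        prec = _safe_div(tp, tp + fp, f"precision_{name}", undefined)
        rec = _safe_div(tp, tp + fn, f"recall_{name}", undefined)
        f1 = _safe_div(2 * prec * rec, prec + rec, f"f1_{name}", undefined)
        iou = _safe_div(tp, tp + fp + fn, f"iou_{name}", undefined)
        per_class[name] = {
            "TP": tp, "FP": fp, "FN": fn,
            "precision": prec, "recall": rec, "f1": f1, "iou": iou,
        }
        precs.append(prec); recs.append(rec); f1s.append(f1); ious.append(iou)
    return SemanticReport(
        per_class=per_class,
        mean_precision=float(np.mean(precs)),
        mean_recall=float(np.mean(recs)),
        mean_f1=float(np.mean(f1s)),
        mean_iou=float(np.mean(ious)),
        undefined=undefined,
    )


def instance_iou(set_a: Set[int], set_b: Set[int]) -> float:
    """Point-level IoU of two index sets; 0 when both are empty."""
    a, b = set(set_a), set(set_b)
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


def mcov(true_instances: Sequence[Set[int]], pred_instances: Sequence[Set[int]]) -> float:
    """Mean coverage: average over ground-truth instances of the best IoU
    achieved by any predicted instance (no one-to-one constraint)."""
    if len(true_instances) == 0:
        raise ValueError("need at least one ground-truth instance")
    if len(pred_instances) == 0:
        return 0.0
    total = 0.0
    for gt in true_instances:
        total += max(instance_iou(gt, pr) for pr in pred_instances)
    return total / len(true_instances)


def _greedy_match(iou_matrix: np.ndarray, threshold: float) -> List[Tuple[int, int]]:
    """One-to-one matching by descending IoU; pairs at or below the
    threshold never match (strict inequality)."""
    G, P = iou_matrix.shape
    order = np.argsort(-iou_matrix, axis=None, kind="stable")
    used_g = np.zeros(G, dtype=bool)
    used_p = np.zeros(P, dtype=bool)
    pairs: List[Tuple[int, int]] = []
    for flat in order:
        g, p = divmod(int(flat), P)
        if iou_matrix[g, p] <= threshold:
            break
        if used_g[g] or used_p[p]:
            continue
        used_g[g] = used_p[p] = True
        pairs.append((g, p))
    return pairs


def instance_pr(
    true_instances: Sequence[Set[int]],
    pred_instances: Sequence[Set[int]],
    threshold: float = 0.5,
) -> InstanceReport:
    """Instance precision/recall at IoU > threshold, plus mCov."""
    if len(true_instances) == 0:
        raise ValueError("need at least one ground-truth instance")
    G, P = len(true_instances), len(pred_instances)
    undefined: List[str] = []
    if P == 0:
        undefined.append("precision_ins")
        return InstanceReport(T=0, P_pred=0, G=G, precision_ins=0.0,
                              recall_ins=0.0, mcov=0.0, undefined=undefined)
    iou_matrix = np.array(
        [[instance_iou(gt, pr) for pr in pred_instances] for gt in true_instances]
    )
    T = len(_greedy_match(iou_matrix, threshold))
    return InstanceReport(
        T=T,
        P_pred=P,
        G=G,
        precision_ins=T / P,
        recall_ins=T / G,
        mcov=float(np.mean(iou_matrix.max(axis=1))),
        undefined=undefined,
    )


def instances_from_labels(instance_labels: np.ndarray) -> List[Set[int]]:
    """Convert a per-point instance-id vector into a list of index sets
    (ids < 0, i.e. branch/unassigned, are skipped)."""
    labels = np.asarray(instance_labels)
    return [set(np.flatnonzero(labels == i).tolist()) for i in np.unique(labels) if i >= 0]
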