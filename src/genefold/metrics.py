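"""Binary-classification evaluation: confusion counts, accuracy, MSE, AUC.

Conventions: malignant = +1 (positive), benign = -1 (negative).
Accuracy is reported as a percentage, ``(TP+TN)/(TP+TN+FP+FN) * 100``.
MSE operates on the +/-1 *class codes* (not probabilities), so a single
misclassification contributes ``(2)^2 = 4`` and MSE equals four times the
error rate.  AUC uses the rank (Mann-Whitney) formulation — the
probability that a uniformly chosen positive outranks a uniformly chosen
negative, ties counted one half — which is exact under ties.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import InputError

__all__ = ["ConfusionCounts", "confusion", "accuracy", "mse", "roc_auc", "report"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _as_signs(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=int)
    if a.ndim != 1 or a.size < 1:
        raise InputError(f"{name} must be a non-empty 1-D vector")
    if not np.isin(a, (-1, 1)).all():
        raise InputError(f"{name} must contain only +1/-1 labels")
    return a


def confusion(pred, obs) -> ConfusionCounts:
    """Count TP/TN/FP/FN with malignant = +1 and benign = -1."""
    p = _as_signs(pred, "pred")
    o = _as_signs(obs, "obs")
    if p.shape != o.shape:
        raise InputError(f"length mismatch: {p.shape[0]} predictions, {o.shape[0]} observations")
    return ConfusionCounts(
        tp=int(((p == 1) & (o == 1)).sum()),
        tn=int(((p == -1) & (o == -1)).sum()),
        fp=int(((p == 1) & (o == -1)).sum()),
        fn=int(((p == -1) & (o == 1)).sum()),
    )


def accuracy(c: ConfusionCounts) -> float:
    """Percent of correctly classified instances."""
    if c.total == 0:
        raise InputError("accuracy undefined on zero samples")
    return 100.0 * (c.tp + c.tn) / c.total


def mse(pred, obs) -> float:
    """Mean squared deviation of predicted from observed class codes."""
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape or p.ndim != 1 or p.size < 1:
        raise InputError("pred and obs must be equal-length non-empty vectors")
    return float(np.mean((p - o) ** 2))


def roc_auc(scores, obs) -> float:
    """Rank-based AUC: P(score_pos > score_neg) with ties counted 1/2."""
    s = np.asarray(scores, dtype=float)
    o = _as_signs(obs, "obs")
    if s.shape != o.shape:
        raise InputError("scores and labels must have equal length")
    n_pos = int((o == 1).sum())
    n_neg = int((o == -1).sum())
    if n_pos == 0 or n_neg == 0:
        raise InputError("AUC needs both classes present")
    ranks = rankdata(s)  # average ranks handle ties exactly
    u = ranks[o == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def report(pred, obs, scores=None) -> dict:
    """Aggregate metrics report (accuracy %, MSE, AUC, confusion table)."""
    c = confusion(pred, obs)
    out = {
        "accuracy_percent": accuracy(c),
        "mse": mse(pred, obs),
        "confusion": {"TP": c.tp, "TN": c.tn, "FP": c.fp, "FN": c.fn},
    }
    if scores is not None:
        out["auc"] = roc_auc(scores, obs)
    return out


def report_text(rep: dict) -> str:
    """Aligned plain-text rendering of a metrics report."""
    c = rep["confusion"]
    lines = [
        f"accuracy : {rep['accuracy_percent']:8.2f} %",
        f"MSE      : {rep['mse']:8.4f}",
    ]
    if "auc" in rep:
        lines.append(f"AUC      : {rep['auc']:8.4f}")
    lines += [
        "confusion:",
        "            pred M   pred B",
        f"  obs M  {c['TP']:8d} {c['FN']:8d}",
        f"  obs B  {c['FP']:8d} {c['TN']:8d}",
    ]
    return "\n".join(lines) + "\n"


def report_json(rep: dict) -> str:
    return json.dumps(rep, indent=2)
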