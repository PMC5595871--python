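"""Turning inconsistency maps into segmentations and scoring them.

Thresholding psi gives a binary degeneration mask; against a reference
labeling we report the empirical ROC curve with its trapezoidal AUC, the
best-threshold pixelwise accuracy, and the Dice overlap.  The ROC is the
plain empirical one over all distinct score values (no binormal fit).
"""

from __future__ import annotations

import numpy as np
from sklearn import metrics as _skm

__all__ = ["threshold_map", "roc_auc", "best_accuracy", "dice"]


def _as_scores(psi) -> np.ndarray:
    """Accept an InconsistencyMap, a grid, or a flat score array."""
    psi = getattr(psi, "psi", psi)
    return np.asarray(psi, dtype=np.float64)


def threshold_map(psi, tau: float) -> np.ndarray:
    """Binary mask psi > tau (strict inequality), tau in [0, 1]."""
    if not 0 <= tau <= 1:
        raise ValueError("tau must lie in [0, 1]")
    return _as_scores(psi) > tau


def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(bool).ravel()
    if labels.all() or not labels.any():
        raise ValueError("labels must contain both classes")
    return labels


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """Empirical ROC and trapezoidal AUC of scores against binary labels.

    Returns (points, auc) where points has one (fpr, tpr, tau) row per
    distinct score value (ties grouped into a single vertex)."""
    scores = _as_scores(scores).ravel()
    labels = _check_two_classes(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    fpr, tpr, thr = _skm.roc_curve(labels, scores, drop_intermediate=False)
    auc = float(_skm.auc(fpr, tpr))
    return np.column_stack([fpr, tpr, thr]), auc


def best_accuracy(scores, labels) -> tuple[float, float]:
    """Threshold maximizing pixelwise accuracy of the rule (score > tau).

    Scans every distinct score value as tau, plus one value below the
    minimum (the all-positive rule; the maximum score already yields the
    all-negative rule), so a trivial classifier is always in the scan.
    Ties break toward the smallest tau."""
    scores = _as_scores(scores).ravel()
    labels = _check_two_classes(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    cand = np.unique(scores)
    cand = np.concatenate([[cand[0] - 1.0], cand])
    best_tau, best_acc = cand[0], -1.0
    for tau in cand:
        acc = float(np.mean((scores > tau) == labels))
        if acc > best_acc:
            best_tau, best_acc = float(tau), acc
    return best_tau, best_acc


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|a&b| / (|a|+|b|); 1.0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
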