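"""Decoder evaluation: balanced accuracy, F-score, trajectory cosine
similarity, and the two-sample t-test used to compare feature approaches.

Balanced accuracy (mean of per-class recalls) is the headline metric
because idle windows heavily outnumber movement windows in motor tasks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "balanced_accuracy",
    "fscore",
    "cosine_similarity",
    "compare_models",
    "EvalReport",
    "evaluate_steps",
]


def balanced_accuracy(truth, pred) -> float:
    """Mean of per-class recalls over the classes present in ``truth``."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.size == 0:
        raise ValueError("empty input")
    if truth.shape != pred.shape:
        raise ValueError("truth and prediction lengths differ")
    recalls = [
        np.mean(pred[truth == c] == c) for c in np.unique(truth)
    ]
    return float(np.mean(recalls))


def fscore(truth, pred, positive_class) -> float:
    """F1 for the positive class; 0 when precision or recall is undefined."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.size == 0:
        raise ValueError("empty input")
    tp = np.sum((pred == positive_class) & (truth == positive_class))
    fp = np.sum((pred == positive_class) & (truth != positive_class))
    fn = np.sum((pred != positive_class) & (truth == positive_class))
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return float(2 * precision * recall / (precision + recall))


def cosine_similarity(pred_traj: np.ndarray, true_traj: np.ndarray) -> float:
    """Mean per-window cosine between predicted and target coordinates.

    Inputs are ``(T, ...)`` arrays flattened per window; windows whose true
    vector is zero (no movement target) are skipped.  All-zero truth has no
    defined direction and is reported as NaN.
    """
    pred = np.asarray(pred_traj, dtype=float).reshape(len(pred_traj), -1)
    true = np.asarray(true_traj, dtype=float).reshape(len(true_traj), -1)
    if pred.shape != true.shape:
        raise ValueError("trajectory shapes differ")
    true_norm = np.linalg.norm(true, axis=1)
    keep = true_norm > 0
    if not keep.any():
        return float("nan")
    pred_norm = np.linalg.norm(pred, axis=1)
    denom = pred_norm[keep] * true_norm[keep]
    dots = np.einsum("ij,ij->i", pred[keep], true[keep])
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.where(denom > 0, dots / denom, 0.0)
    return float(np.mean(cos))


def compare_models(acc_a, acc_b, paired: bool = False) -> float:
    """Two-sided p-value of the t-test on per-session accuracies.

    Welch's unequal-variance test by default; ``paired=True`` switches to a
    paired test when both models were run on the same sessions.
    """
    acc_a = np.asarray(acc_a, dtype=float)
    acc_b = np.asarray(acc_b, dtype=float)
    if len(acc_a) < 2 or len(acc_b) < 2:
        raise ValueError("need at least two sessions per model")
    # degenerate case scipy leaves as 0/0: no variance anywhere
    if acc_a.var() == 0 and acc_b.var() == 0:
        return 1.0 if acc_a.mean() == acc_b.mean() else 0.0
    if paired:
        res = stats.ttest_rel(acc_a, acc_b)
    else:
        res = stats.ttest_ind(acc_a, acc_b, equal_var=False)
    return float(res.pvalue)


@dataclass
class EvalReport:
    balanced_accuracy: float
    fscore_per_class: dict
    cosine_per_hand: list | None
    n_windows: int


def evaluate_steps(steps, session, window_slice=slice(None)) -> EvalReport:
    """Score a decoded step sequence against a labelled session."""
    truth = np.asarray(session.state_labels)[window_slice]
    pred = np.array([s.state for s in steps])[window_slice]
    report = EvalReport(
        balanced_accuracy=balanced_accuracy(truth, pred),
        fscore_per_class={int(c): fscore(truth, pred, c) for c in np.unique(truth)},
        cosine_per_hand=None,
        n_windows=len(truth),
    )
    if session.trajectory_targets is not None and steps and steps[0].trajectory is not None:
        true = np.asarray(session.trajectory_targets)[window_slice]
        pred_traj = np.array([s.trajectory for s in steps])[window_slice]
        report.cosine_per_hand = [
            cosine_similarity(pred_traj[:, h, :], true[:, h, :]) for h in range(2)
        ]
    return report
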