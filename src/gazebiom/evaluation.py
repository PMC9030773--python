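"""Biometric evaluation: accuracy, Rank-k identification rate, CMC, ROC, EER.

Rank-k identification rate is the fraction of test segments whose true
identity is among the k highest-scored candidates; the CMC curve traces it
over k = 1..n_subjects and accuracy is its k = 1 point.  The ROC sweeps a
threshold over match scores; the equal error rate is the operating point
where the false positive rate equals the false negative rate (found by
linear interpolation between adjacent thresholds).  For identification runs
the ROC is micro-averaged one-vs-rest over candidate scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .recognition import RunResult


@dataclass(frozen=True)
class CmcCurve:
    ranks: np.ndarray        # 1..n_classes
    identification_rate: np.ndarray


@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    eer: float


def _ranking_matrix(run: RunResult) -> np.ndarray:
    """Candidate indices per test segment, best first; ties by class order."""
    # stable sort on -score keeps earlier (lower class id) columns first on ties
    return np.argsort(-run.scores, axis=1, kind="stable")


def rank_k_ir(run: RunResult, k: int) -> float:
    """Fraction of test segments whose true identity is in the top-k candidates."""
    if not 1 <= k <= len(run.classes):
        raise ValueError(f"k must be in 1..{len(run.classes)}")
    order = _ranking_matrix(run)
    true_idx = np.searchsorted(run.classes, run.y_true)
    hit = (order[:, :k] == true_idx[:, None]).any(axis=1)
    return float(hit.mean())


def cmc_curve(run: RunResult) -> CmcCurve:
    """Rank-k identification rate for every k (nondecreasing, ends at 1)."""
    order = _ranking_matrix(run)
    true_idx = np.searchsorted(run.classes, run.y_true)
    rank_of_truth = np.argmax(order == true_idx[:, None], axis=1)  # 0-based
    n = len(run.classes)
    ir = np.cumsum(np.bincount(rank_of_truth, minlength=n)) / len(run.y_true)
    return CmcCurve(ranks=np.arange(1, n + 1), identification_rate=ir)


def roc_eer(scores, labels) -> RocCurve:
    """ROC over a threshold sweep plus the interpolated equal error rate."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both positive and negative labels")
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    fnr = 1.0 - tpr
    diff = fpr - fnr
    # first index where FPR >= FNR; interpolate within the crossing segment
    i = int(np.argmax(diff >= 0))
    if i == 0:
        eer = float((fpr[0] + fnr[0]) / 2)
    else:
        d0, d1 = diff[i - 1], diff[i]
        w = 0.0 if d1 == d0 else -d0 / (d1 - d0)
        eer = float((1 - w) * fpr[i - 1] + w * fpr[i])
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, eer=eer)


def identification_roc(run: RunResult) -> RocCurve:
    """Micro-averaged one-vs-rest ROC over all candidate scores."""
    true_idx = np.searchsorted(run.classes, run.y_true)
    onehot = np.zeros_like(run.scores, dtype=int)
    onehot[np.arange(len(true_idx)), true_idx] = 1
    return roc_eer(run.scores.ravel(), onehot.ravel())


def verification_roc(run: RunResult) -> RocCurve:
    """ROC of a verification run (genuine-class probability as the score)."""
    if run.scenario != "verification":
        raise ValueError("expected a verification run")
    return roc_eer(run.scores[:, 1], run.y_true)


def chance_level(n_subjects: int) -> float:
    """Expected accuracy of a uniform-random identifier: 1/n."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    return 1.0 / n_subjects


def summarize(run: RunResult) -> dict:
    """Per-run metric summary (JSON-serializable)."""
    out = {
        "scenario": run.scenario, "cv_scheme": run.cv_scheme,
        "feature_set": run.feature_set, "t_win": run.t_win,
        "n_test_segments": int(len(run.y_true)),
        "accuracy": run.accuracy,
    }
    if run.scenario == "identification":
        out["n_subjects"] = int(len(run.classes))
        out["chance_level"] = chance_level(len(run.classes))
        out["rank_5_ir"] = rank_k_ir(run, min(5, len(run.classes)))
        out["eer"] = identification_roc(run).eer
    else:
        out["eer"] = verification_roc(run).eer
    return out


__all__ = [
    "CmcCurve", "RocCurve",
    "rank_k_ir", "cmc_curve", "roc_eer",
    "identification_roc", "verification_roc", "chance_level", "summarize",
]
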