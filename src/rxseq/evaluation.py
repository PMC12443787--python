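"""Discrimination metrics: per-event AUC and sensitivity/specificity."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .synthetic import EVENT_NAMES


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count one half.

    Returns NaN when only one class is present (the AUC is undefined).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def mean_auc(scores, labels) -> float:
    """Unweighted mean AUC over the nine events (NaN events excluded)."""
    scores = np.atleast_2d(scores)
    labels = np.atleast_2d(labels)
    per = [auc(scores[:, e], labels[:, e]) for e in range(scores.shape[1])]
    per = [a for a in per if not np.isnan(a)]
    return float(np.mean(per)) if per else float("nan")


def sensitivity_specificity(scores, labels, threshold: float = 0.5):
    """(sensitivity, specificity) at a fixed decision threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return sens, spec


def evaluation_report(scores, labels, threshold: float = 0.5) -> dict:
    """Per-event AUC, sensitivity/specificity and the balance statistic."""
    scores = np.atleast_2d(scores)
    labels = np.atleast_2d(labels)
    report = {"events": {}, "threshold": threshold}
    for e, name in enumerate(EVENT_NAMES[: scores.shape[1]]):
        a = auc(scores[:, e], labels[:, e])
        sens, spec = sensitivity_specificity(scores[:, e], labels[:, e], threshold)
        report["events"][name] = {
            "auc": a,
            "sensitivity": sens,
            "specificity": spec,
            "balance": abs(sens - spec) if not (np.isnan(sens) or np.isnan(spec)) else float("nan"),
            "n_positive": int(labels[:, e].sum()),
        }
    report["mean_auc"] = mean_auc(scores, labels)
    return report
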