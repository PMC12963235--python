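"""Evaluation metrics and the seed-replicate statistical protocol.

Conventions: AUROC uses the rank/concordance (mid-rank tie) estimator;
AUPRC is step-wise average precision without interpolation; F1 uses a fixed
0.5 threshold and is 0 when precision + recall is 0; replicate tables report
mean and sample (n-1) standard deviation; significance is the classical
two-sided paired t-test on per-seed values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from ledgerfed.errors import AggregationError, MetricError


@dataclass
class MetricsReport:
    auroc: float
    auprc: float
    f1: float
    brier: float
    n_episodes: int
    threshold: float = 0.5
    seed: int | None = None
    params: int | None = None
    flops: int | None = None

    def as_dict(self) -> dict:
        return dict(auroc=self.auroc, auprc=self.auprc, f1=self.f1, brier=self.brier,
                    n_episodes=self.n_episodes, threshold=self.threshold, seed=self.seed)


def _check(labels, scores):
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise MetricError("labels and scores must be 1-d arrays of equal length")
    return labels, scores


def auroc(labels, scores) -> float:
    """Probability of concordance with ties counted half (mid-rank)."""
    labels, scores = _check(labels, scores)
    if len(np.unique(labels)) < 2:
        raise MetricError("AUROC undefined on single-class labels")
    return float(roc_auc_score(labels, scores))


def auprc(labels, scores) -> float:
    """Step-wise average precision (no linear interpolation)."""
    labels, scores = _check(labels, scores)
    if labels.sum() == 0:
        raise MetricError("AUPRC undefined without positives")
    return float(average_precision_score(labels, scores))


def f1_at_threshold(labels, probabilities, threshold: float = 0.5) -> float:
    labels, probs = _check(labels, probabilities)
    pred = probs >= threshold
    tp = float(np.sum(pred & (labels == 1)))
    fp = float(np.sum(pred & (labels == 0)))
    fn = float(np.sum(~pred & (labels == 1)))
    denom = 2 * tp + fp + fn
    return 0.0 if denom == 0 else 2 * tp / denom


def brier(labels, probabilities) -> float:
    """Mean squared difference between predicted probability and outcome."""
    labels, probs = _check(labels, probabilities)
    if np.any((probs < 0) | (probs > 1)):
        raise MetricError("probabilities must lie in [0, 1]")
    return float(np.mean((probs - labels) ** 2))


def compute_report(labels, probabilities, threshold: float = 0.5,
                   seed: int | None = None) -> MetricsReport:
    return MetricsReport(
        auroc=auroc(labels, probabilities),
        auprc=auprc(labels, probabilities),
        f1=f1_at_threshold(labels, probabilities, threshold),
        brier=brier(labels, probabilities),
        n_episodes=len(labels),
        threshold=threshold,
        seed=seed,
    )


def aggregate_runs(reports: list[MetricsReport]) -> dict[str, tuple[float, float]]:
    """Per-metric (mean, sample sd) over seed replicates; needs >= 2 runs."""
    if len(reports) < 2:
        raise AggregationError("need at least 2 runs to aggregate")
    out = {}
    for metric in ("auroc", "auprc", "f1", "brier"):
        vals = np.array([getattr(r, metric) for r in reports], dtype=float)
        sd = 0.0 if np.all(vals == vals[0]) else float(vals.std(ddof=1))
        out[metric] = (float(vals.mean()), sd)
    return out


def paired_t_test(a, b) -> tuple[float, float]:
    """Two-sided paired t-test on per-seed values.

    All-zero differences give (t=0, p=1); zero-variance nonzero differences
    are degenerate and reported as (sign(d)*inf, 0.0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise MetricError("need paired 1-d samples of equal length >= 2")
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0
    if np.std(d, ddof=1) == 0:
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
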