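"""Model evaluation: ROC/AUC, thresholded confusion metrics, marginal responses.

Negatives are the available points *not* labeled used (the confusion-table
convention), even though the model's fitting background includes the used
points; both counts are carried so either convention can be reported.
Threshold comparisons are inclusive (score >= threshold is "habitat").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def n_used(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.n_used + self.n_negative


def confusion(
    used_scores: np.ndarray, negative_scores: np.ndarray, threshold: float,
) -> ConfusionMatrix:
    """Confusion matrix at a threshold (score >= threshold is positive).

    ``negative_scores`` are the available points not labeled used; when
    holding the full background, filter the used points out first (the
    confusion-table convention keeps the two samples disjoint).
    """
    used_scores = np.asarray(used_scores, dtype=float)
    negative_scores = np.asarray(negative_scores, dtype=float)
    if used_scores.size == 0:
        raise ValueError("used sample is empty")
    tp = int((used_scores >= threshold).sum())
    fn = used_scores.size - tp
    fp = int((negative_scores >= threshold).sum())
    tn = negative_scores.size - fp
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def sensitivity(cm: ConfusionMatrix) -> float:
    """TP / (TP + FN)."""
    if cm.tp + cm.fn == 0:
        raise ZeroDivisionError("no used points")
    return cm.tp / (cm.tp + cm.fn)


def ppv(cm: ConfusionMatrix) -> float:
    """Positive predictive value, TP / (TP + FP)."""
    if cm.tp + cm.fp == 0:
        raise ZeroDivisionError("no predicted positives")
    return cm.tp / (cm.tp + cm.fp)


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa: 2(TP*TN - FN*FP) / ((TP+FP)(FP+TN) + (TP+FN)(FN+TN)).

    Computed in exact integer arithmetic before the final division.
    """
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    num = 2 * (tp * tn - fn * fp)
    den = (tp + fp) * (fp + tn) + (tp + fn) * (fn + tn)
    if den == 0:
        raise ZeroDivisionError("degenerate confusion matrix")
    return num / den


def kappa_parts(cm: ConfusionMatrix) -> tuple[int, int]:
    """(numerator, denominator) of kappa as exact integers."""
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    return 2 * (tp * tn - fn * fp), (tp + fp) * (fp + tn) + (tp + fn) * (fn + tn)


def auc(positive_scores: np.ndarray, negative_scores: np.ndarray) -> float:
    """Mann-Whitney AUC: P(random positive > random negative), ties count half."""
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score samples must be nonempty")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def auc_bruteforce(positive_scores: np.ndarray, negative_scores: np.ndarray) -> float:
    """O(n_pos * n_neg) pair-counting oracle for auc()."""
    pos = np.asarray(positive_scores, dtype=float)[:, None]
    neg = np.asarray(negative_scores, dtype=float)[None, :]
    wins = (pos > neg).sum() + 0.5 * (pos == neg).sum()
    return float(wins / (pos.shape[0] * neg.shape[1]))


@dataclass
class MarginalCurve:
    covariate: str
    values: np.ndarray              # covariate grid
    hsi: np.ndarray                 # HSI of the point model (or replicate mean)
    hsi_sd: np.ndarray | None = None


def marginal_response(
    model, covariate: str, available_raw: np.ndarray, n_points: int = 100,
    replicate_models: list | None = None,
) -> MarginalCurve:
    """HSI response to one covariate, others held at available means.

    The covariate sweeps its available-sample range at ``n_points``; with
    bootstrap replicate models the curve is the replicate mean with an SD
    band.
    """
    names = model.covariate_names
    if covariate not in names:
        raise KeyError(f"unknown covariate {covariate!r}; model has {names}")
    j = names.index(covariate)
    available_raw = np.atleast_2d(np.asarray(available_raw, dtype=float))
    base = available_raw.mean(axis=0)
    sweep = np.linspace(available_raw[:, j].min(), available_raw[:, j].max(),
                        n_points)
    rows = np.tile(base, (n_points, 1))
    rows[:, j] = sweep
    if replicate_models:
        preds = np.stack([m.predict_logistic(rows) for m in replicate_models])
        return MarginalCurve(covariate, sweep, preds.mean(axis=0), preds.std(axis=0))
    return MarginalCurve(covariate, sweep, model.predict_logistic(rows))
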