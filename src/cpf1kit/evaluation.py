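"""Labeling by efficacy cutoffs, extremes train/test split, external
cross-validation and classification metrics.

Training labels come from the ranked indel frequencies: records are sorted
descending, the top fraction becomes the positive class ("most effective
guides" on-target, "high activity off-target sites" off-target), the bottom
fraction the negative class, and the middle is excluded.  With 1251 records
and top/bottom 20% this reproduces the 500-record training set (250 + 250)
and 751-record test set.

Metrics are ROC/AUC (Mann-Whitney rank statistic with the half-tie
convention), F1 = 2TP / (2TP + FP + FN) at a score threshold, and Spearman
rank correlation for the held-out regression check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "MetricsReport",
    "CVReport",
    "label_by_cutoffs",
    "split_extremes",
    "roc_auc",
    "f1_at_threshold",
    "spearman_rho",
    "evaluate_scores",
    "external_cv",
    "cutoff_grid",
]

# trainer callback: (X_train, y_train) -> score function over X
Trainer = Callable[[np.ndarray, np.ndarray], Callable[[np.ndarray], np.ndarray]]


@dataclass
class MetricsReport:
    """Classification metrics for one set of scores and binary labels."""

    auc: float
    f1: float
    tp: int
    fp: int
    fn: int
    tn: int
    fpr_curve: np.ndarray
    tpr_curve: np.ndarray
    spearman: float | None = None

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn)

    def curve_frame(self) -> pd.DataFrame:
        """ROC points as a two-column frame for plotting or TSV export."""
        return pd.DataFrame({"fpr": self.fpr_curve, "tpr": self.tpr_curve})


@dataclass
class CVReport:
    """Per-fold AUCs of an external cross-validation."""

    fold_aucs: list[float]
    fold_sizes: list[int]

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.fold_aucs, ddof=1))

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fold": range(1, len(self.fold_aucs) + 1),
             "size": self.fold_sizes, "auc": self.fold_aucs}
        )


def _ranked(records: Sequence) -> list:
    # stable descending sort by indel frequency; ties keep input order
    return sorted(records, key=lambda r: -r.indel_frequency)


def label_by_cutoffs(records: Sequence, top_frac: float, bottom_frac: float):
    """Label the efficacy extremes of a ranked dataset.

    Records are sorted descending by indel frequency; the top
    ``floor(top_frac * n)`` become class 1, the bottom
    ``floor(bottom_frac * n)`` class 0, and the middle is dropped.

    Returns
    -------
    (records, labels) : the selected records (top block first) and their
    0/1 labels as an int array.
    """
    if not (0 < top_frac and 0 < bottom_frac and top_frac + bottom_frac <= 1):
        raise ValueError(
            f"need 0 < top_frac, bottom_frac and top+bottom <= 1, "
            f"got {top_frac}, {bottom_frac}"
        )
    n = len(records)
    n_top = int(np.floor(top_frac * n))
    n_bot = int(np.floor(bottom_frac * n))
    if n_top < 1 or n_bot < 1:
        raise ValueError(
            f"cutoffs select an empty class (n={n}, top={n_top}, bottom={n_bot})"
        )
    ranked = _ranked(records)
    chosen = ranked[:n_top] + ranked[n - n_bot :]
    labels = np.array([1] * n_top + [0] * n_bot, dtype=np.int64)
    return chosen, labels


def split_extremes(records: Sequence, top_frac: float = 0.2, bottom_frac: float = 0.2):
    """Split ranked records into labeled extremes (train) and the middle (test).

    The train set carries binary labels for classification; the held-out
    middle keeps its raw indel frequencies for correlation analysis.
    Train and test partition the input.
    """
    train_records, labels = label_by_cutoffs(records, top_frac, bottom_frac)
    n = len(records)
    n_top = int(np.floor(top_frac * n))
    n_bot = int(np.floor(bottom_frac * n))
    test_records = _ranked(records)[n_top : n - n_bot]
    return train_records, labels, test_records


def roc_auc(scores, labels):
    """AUC plus the ROC curve.

    Returns
    -------
    (auc, fpr, tpr) : AUC equals the rank statistic
    P(score_pos > score_neg) + 0.5 P(equal); both classes must be present.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class; AUC undefined")
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(roc_auc_score(labels, scores)), fpr, tpr


def f1_at_threshold(scores, labels, threshold: float = 0.5) -> float:
    """F1 = 2TP / (2TP + FP + FN); predictions positive at score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def spearman_rho(predicted, observed) -> float:
    """Spearman rank correlation with average-rank tie handling."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if len(predicted) != len(observed):
        raise ValueError("length mismatch")
    if len(predicted) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(predicted) == 0 or np.ptp(observed) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    return float(spearmanr(predicted, observed).statistic)


def evaluate_scores(scores, labels, threshold: float = 0.5,
                    observed=None) -> MetricsReport:
    """Full metrics report for one score vector."""
    auc, fpr, tpr = roc_auc(scores, labels)
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    rho = spearman_rho(scores, observed) if observed is not None else None
    return MetricsReport(
        auc=auc, f1=f1_at_threshold(scores, labels, threshold),
        tp=tp, fp=fp, fn=fn, tn=tn, fpr_curve=fpr, tpr_curve=tpr, spearman=rho,
    )


def external_cv(X, y, trainer: Trainer, k: int = 5, seed: int = 0) -> CVReport:
    """k-fold external cross-validation.

    The data are divided into k near-equal folds (seeded, stratified so
    both classes appear in every fold); each fold is scored only by a model
    trained on the other k-1 folds, so every record is predicted exactly
    once by a model that never saw it.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if len(X) < k:
        raise ValueError(f"n={len(X)} smaller than k={k}")
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes for cross-validation")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_aucs, fold_sizes = [], []
    for train_idx, test_idx in skf.split(X, y):
        score_fn = trainer(X[train_idx], y[train_idx])
        auc, _, _ = roc_auc(score_fn(X[test_idx]), y[test_idx])
        fold_aucs.append(auc)
        fold_sizes.append(len(test_idx))
    return CVReport(fold_aucs=fold_aucs, fold_sizes=fold_sizes)


def cutoff_grid(
    records: Sequence,
    encoder: Callable[[object], np.ndarray],
    trainer: Trainer,
    top_fracs: Sequence[float] = tuple(np.arange(0.05, 0.46, 0.05)),
    bottom_fracs: Sequence[float] = (0.60, 0.65, 0.70, 0.75, 0.80),
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean-CV-AUC for every (top, bottom) efficacy-cutoff combination.

    The default 9 x 5 grid yields 45 trained models.  ``bottom_fracs`` are
    expressed as the fraction labeled negative counted from the bottom of
    the ranking.  Combinations that are infeasible (fractions exceeding 1,
    or an empty class) are reported with status ``skipped`` and NaN AUC.
    """
    rows = []
    for tf in top_fracs:
        for bf in bottom_fracs:
            entry = {"top_frac": round(float(tf), 4),
                     "bottom_frac": round(float(bf), 4)}
            try:
                if tf + bf > 1:
                    raise ValueError("fractions exceed 1")
                chosen, labels = label_by_cutoffs(records, tf, bf)
                X = np.stack([encoder(r) for r in chosen])
                report = external_cv(X, labels, trainer, k=k, seed=seed)
                entry.update(mean_auc=report.mean_auc, sd_auc=report.sd_auc,
                             n=len(labels), status="ok")
            except ValueError as exc:
                entry.update(mean_auc=np.nan, sd_auc=np.nan, n=0,
                             status=f"skipped: {exc}")
            rows.append(entry)
    return pd.DataFrame(rows)
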