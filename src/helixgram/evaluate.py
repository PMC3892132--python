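"""ROC/AUC evaluation and cross-validation schemes.

AUC here is the rank-based probability that a positive outscores a
negative (ties counted one half), which equals the trapezoidal area
under the empirical ROC step curve.  Leave-one-out CV trains on all but
one positive and measures how much of the negative set scores below the
held-out positive -- in that scheme the per-sample AUC *is* the
specificity at the positive's score.  Four-fold CV partitions positives
into contiguous blocks by identifier sort order, trains several grammars
per fold and reports single, combined and best-single AUCs.  Vertical
averaging summarizes several ROC curves on a fixed false-positive-rate
grid with normal-approximation confidence half-widths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .sequences import HelixPairSequence

__all__ = [
    "ROCCurve",
    "AveragedROC",
    "LOOCVResult",
    "KFoldResult",
    "roc_auc",
    "loocv",
    "kfold_cv",
    "vertical_average",
    "prf_at_fpr",
]


@dataclass(frozen=True)
class ROCCurve:
    """An empirical ROC step curve with its AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int

    def tpr_at(self, fpr_grid: np.ndarray) -> np.ndarray:
        """Step-curve TP rate at given FP rates (largest realized point <= x)."""
        fpr_grid = np.asarray(fpr_grid, dtype=float)
        idx = np.searchsorted(self.fpr, fpr_grid, side="right") - 1
        idx = np.clip(idx, 0, len(self.fpr) - 1)
        return self.tpr[idx]


@dataclass(frozen=True)
class AveragedROC:
    """Vertically averaged ROC band: grid, mean TP rate, CI half-widths."""

    grid: np.ndarray
    mean_tpr: np.ndarray
    halfwidth: np.ndarray
    n_curves: int


@dataclass(frozen=True)
class LOOCVResult:
    """Per-held-out-positive AUCs with their mean and spread."""

    sample_ids: tuple[str, ...]
    aucs: np.ndarray
    high_specificity_threshold: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def sd(self) -> float:
        return float(np.std(self.aucs, ddof=1)) if len(self.aucs) > 1 else 0.0

    @property
    def high_specificity_ids(self) -> tuple[str, ...]:
        return tuple(
            sid
            for sid, a in zip(self.sample_ids, self.aucs)
            if a >= self.high_specificity_threshold
        )


@dataclass(frozen=True)
class KFoldResult:
    """Per-fold single/combined/best-single AUCs and their averages."""

    fold_single_aucs: tuple[tuple[float, ...], ...]
    fold_combined_auc: tuple[float, ...]
    fold_best_auc: tuple[float, ...]

    @property
    def mean_combined(self) -> float:
        return float(np.mean(self.fold_combined_auc))

    @property
    def mean_best(self) -> float:
        return float(np.mean(self.fold_best_auc))


def roc_auc(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> ROCCurve:
    """ROC curve and AUC from positive and negative score sets."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    s = np.concatenate([pos, neg])
    auc = float(roc_auc_score(y, s))
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    return ROCCurve(fpr=fpr, tpr=tpr, auc=auc, n_pos=pos.size, n_neg=neg.size)


def _per_sample_auc(pos_score: float, neg_scores: np.ndarray) -> float:
    """Fraction of negatives strictly below the positive, ties counted half.

    This equals the specificity at the threshold set by the positive's
    own score, the LOOCV identity.
    """
    below = np.sum(neg_scores < pos_score)
    ties = np.sum(neg_scores == pos_score)
    return float((below + 0.5 * ties) / neg_scores.size)


def loocv(
    train_fn: Callable[[Sequence[HelixPairSequence]], Callable],
    pos_set: Sequence[HelixPairSequence],
    neg_set: Sequence[HelixPairSequence],
    high_specificity_threshold: float = 0.75,
) -> LOOCVResult:
    """Leave-one-out CV over the positive set.

    ``train_fn(train_positives)`` must return a scorer mapping a sequence
    list to a score vector.  Each held-out positive is scored against the
    entire negative set; training failures are re-raised with the
    held-out sample's id attached.
    """
    pos_set = list(pos_set)
    if len(pos_set) < 2:
        raise ValueError("LOOCV requires at least 2 positives")
    aucs = []
    ids = []
    for i, held in enumerate(pos_set):
        rest = pos_set[:i] + pos_set[i + 1 :]
        try:
            scorer = train_fn(rest)
            s_pos = float(np.asarray(scorer([held]))[0])
            s_neg = np.asarray(scorer(list(neg_set)), dtype=float)
        except Exception as exc:
            raise RuntimeError(f"LOOCV training failed holding out {held.id!r}") from exc
        aucs.append(_per_sample_auc(s_pos, s_neg))
        ids.append(held.id)
    return LOOCVResult(
        sample_ids=tuple(ids),
        aucs=np.array(aucs),
        high_specificity_threshold=high_specificity_threshold,
    )


def kfold_cv(
    train_fn: Callable[[Sequence[HelixPairSequence], int], Callable],
    pos_set: Sequence[HelixPairSequence],
    neg_set: Sequence[HelixPairSequence],
    k: int = 4,
    combine: int = 3,
) -> KFoldResult:
    """k-fold CV with folds formed by identifier sort order.

    Positives are sorted by id and split into ``k`` contiguous blocks.
    Per fold, ``combine`` scorers are trained on the other blocks with
    seeds ``0..combine-1``; held-out positives are scored against the
    whole negative set, reporting each scorer's AUC, the AUC of their
    averaged scores (combined classifier) and the best single AUC.
    """
    pos_sorted = sorted(pos_set, key=lambda s: s.id)
    if len(pos_sorted) < k:
        raise ValueError(f"need at least k={k} positives, got {len(pos_sorted)}")
    folds = [list(block) for block in np.array_split(np.array(pos_sorted, dtype=object), k)]
    single_all: list[tuple[float, ...]] = []
    combined_all: list[float] = []
    best_all: list[float] = []
    for f, held in enumerate(folds):
        train_pos = [s for g, block in enumerate(folds) if g != f for s in block]
        pos_mat = []
        neg_mat = []
        for seed in range(combine):
            try:
                scorer = train_fn(train_pos, seed)
            except Exception as exc:
                raise RuntimeError(f"k-fold training failed on fold {f}, seed {seed}") from exc
            pos_mat.append(np.asarray(scorer(held), dtype=float))
            neg_mat.append(np.asarray(scorer(list(neg_set)), dtype=float))
        singles = tuple(
            roc_auc(p, n).auc for p, n in zip(pos_mat, neg_mat)
        )
        combined = roc_auc(np.mean(pos_mat, axis=0), np.mean(neg_mat, axis=0)).auc
        single_all.append(singles)
        combined_all.append(combined)
        best_all.append(max(singles))
    return KFoldResult(
        fold_single_aucs=tuple(single_all),
        fold_combined_auc=tuple(combined_all),
        fold_best_auc=tuple(best_all),
    )


def vertical_average(curves: Sequence[ROCCurve], band: float = 0.1) -> AveragedROC:
    """Average several ROC curves at fixed FP-rate grid points.

    The grid covers [0, 1] in steps of ``band``; the confidence half-width
    at each grid point is the normal approximation
    ``1.96 * sqrt(p * (1 - p) / n)`` with ``p`` the mean TP rate and ``n``
    the number of curves.
    """
    if not curves:
        raise ValueError("need at least one curve")
    grid = np.arange(0.0, 1.0 + band / 2, band)
    tprs = np.stack([c.tpr_at(grid) for c in curves])
    mean_tpr = tprs.mean(axis=0)
    n = len(curves)
    halfwidth = 1.96 * np.sqrt(mean_tpr * (1.0 - mean_tpr) / n)
    return AveragedROC(grid=grid, mean_tpr=mean_tpr, halfwidth=halfwidth, n_curves=n)


def prf_at_fpr(curve: ROCCurve, fpr_thresholds: Sequence[float]) -> pd.DataFrame:
    """Precision/Recall/F1/Accuracy at the realized operating points
    nearest each requested FP-rate threshold (at or below it)."""
    rows = []
    for thr in fpr_thresholds:
        mask = curve.fpr <= thr + 1e-12
        idx = int(np.nonzero(mask)[0][-1]) if mask.any() else 0
        fpr = float(curve.fpr[idx])
        tpr = float(curve.tpr[idx])
        tp = tpr * curve.n_pos
        fp = fpr * curve.n_neg
        fn = (1.0 - tpr) * curve.n_pos
        tn = (1.0 - fpr) * curve.n_neg
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tpr
        f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
        accuracy = (tp + tn) / (curve.n_pos + curve.n_neg)
        rows.append(
            {
                "fpr_threshold": thr,
                "fpr": fpr,
                "precision": precision,
                "recall": recall,
                "f1": f1,
                "accuracy": accuracy,
            }
        )
    return pd.DataFrame(rows)
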