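"""Cross-validated scoring, filter-count grid search, and the score matrix.

The evaluation protocol is five independent shuffled 80/20 splits per
subject, scoring accuracy, Cohen's kappa and ROC-AUC on each held-out 20%.
Per-subject results are condensed into a six-column score matrix —
[mean acc, mean normalised kappa, mean AUC, 1−std(acc), 1−std(kappa_n),
1−std(AUC)] — whose every entry lives in [0, 1]: kappa is mapped to
(κ+1)/2 per fold before aggregation, and standard deviations are replaced
by their complements so that higher is uniformly better.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics import accuracy_score, cohen_kappa_score, roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit

from .model import KCSFCnet

__all__ = [
    "FoldMetrics",
    "compute_metrics",
    "cross_validate",
    "grid_search_nf",
    "build_score_matrix",
    "SCORE_COLUMNS",
]

SCORE_COLUMNS = ["acc", "kappa_n", "auc", "c_std_acc", "c_std_kappa", "c_std_auc"]


@dataclass(frozen=True)
class FoldMetrics:
    """Held-out metrics of one cross-validation fold."""

    fold_id: int
    accuracy: float
    kappa: float
    auc: float | None

    def as_dict(self) -> dict:
        return asdict(self)


def compute_metrics(y_true: np.ndarray, y_prob: np.ndarray,
                    fold_id: int = 0) -> FoldMetrics:
    """Accuracy, Cohen's kappa and ROC-AUC from class-1 probabilities.

    Predictions are thresholded at 0.5 (ties to class 0, the lower index).
    AUC is the probability that a random positive outranks a random
    negative, ties counting one half; it is undefined (None, with a
    warning) when only one class is present.
    """
    y_true = np.asarray(y_true)
    y_prob = np.asarray(y_prob, dtype=float)
    if y_true.shape != y_prob.shape:
        raise ValueError("y_true and y_prob must have the same length")
    if np.any((y_prob < 0) | (y_prob > 1)):
        raise ValueError("y_prob must lie in [0, 1]")
    y_pred = (y_prob > 0.5).astype(int)
    acc = float(accuracy_score(y_true, y_pred))
    kappa = float(cohen_kappa_score(y_true, y_pred))
    if len(np.unique(y_true)) < 2:
        warnings.warn("single-class fold: AUC undefined, reported as missing")
        auc = None
    else:
        auc = float(roc_auc_score(y_true, y_prob))
    return FoldMetrics(fold_id=fold_id, accuracy=acc, kappa=kappa, auc=auc)


def _splits(n: int, y: np.ndarray, n_folds: int, seed: int,
            max_retries: int = 100):
    """Stratified shuffled 80/20 splits with both classes on each side.

    Stratification keeps the class ratio of every training and test part at
    the dataset's ratio; without it, the training-side imbalance of a
    balanced dataset anti-correlates with the held-out side and biases
    null-data accuracy below chance.  A split still missing a class is
    resampled with a bumped seed (logged).
    """
    produced, attempt = 0, 0
    while produced < n_folds:
        if attempt > max_retries:
            raise RuntimeError("could not produce class-complete splits")
        ss = StratifiedShuffleSplit(n_splits=1, test_size=0.2,
                                    random_state=seed + 1000 * attempt + produced)
        train, test = next(ss.split(np.zeros(n), y))
        if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
            warnings.warn(f"split {produced} missing a class; resampled")
            attempt += 1
            continue
        yield train, test
        produced += 1


def cross_validate(X: np.ndarray, y: np.ndarray, model: KCSFCnet | None = None,
                   n_folds: int = 5, seed: int = 0) -> list[FoldMetrics]:
    """Five shuffled 80/20 train/test rounds with a fresh model per fold."""
    X = np.asarray(X)
    y = np.asarray(y)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 trials for 80/20 cross-validation")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    base = model if model is not None else KCSFCnet()
    out = []
    for fold, (train, test) in enumerate(_splits(X.shape[0], y, n_folds, seed)):
        est = clone(base)
        if est.get_params().get("random_state") is None:
            est.set_params(random_state=seed + fold)
        est.fit(X[train], y[train])
        prob1 = est.predict_proba(X[test])[:, 1]
        out.append(compute_metrics(y[test], prob1, fold_id=fold))
    return out


def grid_search_nf(X: np.ndarray, y: np.ndarray, base_model: KCSFCnet | None = None,
                   candidates: tuple[int, ...] = (2, 3, 4), n_folds: int = 5,
                   seed: int = 0) -> tuple[int, dict[int, float], dict[int, list[FoldMetrics]]]:
    """Pick the filter count Nf maximising mean CV accuracy.

    The same seeded splits are reused for every candidate to reduce
    selection variance; exact ties break toward the smaller Nf.  Returns
    the winner, the per-candidate mean accuracies, and every candidate's
    fold metrics (the winner's folds are what enters the score matrix).
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    base = base_model if base_model is not None else KCSFCnet()
    means: dict[int, float] = {}
    folds: dict[int, list[FoldMetrics]] = {}
    for nf in candidates:
        est = clone(base)
        if "n_filters" in est.get_params():
            est.set_params(n_filters=nf)
        fm = cross_validate(X, y, est, n_folds=n_folds, seed=seed)
        folds[nf] = fm
        means[nf] = float(np.mean([f.accuracy for f in fm]))
    best = min(sorted(candidates), key=lambda nf: (-means[nf], nf))
    return best, means, folds


def build_score_matrix(per_subject: dict[str, list[FoldMetrics]]) -> pd.DataFrame:
    """Six-column per-subject score matrix, all entries in [0, 1].

    Kappa is normalised per fold to (κ+1)/2 *before* aggregation so both
    its mean and its complemented spread stay in [0, 1].  Spread is the
    population (n-divisor) standard deviation over folds, replaced by its
    complement 1 − std.
    """
    rows = {}
    for subject, folds in per_subject.items():
        if len(folds) < 2:
            raise ValueError(f"subject {subject!r} has fewer than 2 folds")
        acc = np.array([f.accuracy for f in folds], dtype=float)
        kap = np.array([(f.kappa + 1.0) / 2.0 for f in folds], dtype=float)
        auc = np.array([f.auc for f in folds if f.auc is not None], dtype=float)
        if auc.size == 0:
            raise ValueError(f"subject {subject!r} has no defined AUC")
        stds = [acc.std(), kap.std(), auc.std()]
        assert all(s <= 1.0 for s in stds), "bounded metrics cannot have std > 1"
        row = [acc.mean(), kap.mean(), auc.mean()] + [1.0 - s for s in stds]
        rows[subject] = row
    df = pd.DataFrame.from_dict(rows, orient="index", columns=SCORE_COLUMNS)
    # clip away strictly-numerical excursions only
    out_of_range = (df.values < -1e-9).any() or (df.values > 1 + 1e-9).any()
    if out_of_range:
        raise AssertionError("score matrix entry outside [0,1] beyond tolerance")
    return df.clip(0.0, 1.0)
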