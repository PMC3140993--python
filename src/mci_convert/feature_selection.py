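"""Stability-based feature selection on the NC-vs-AD training groups.

Two procedures are provided:

* :func:`wrapper_select` (MRI, CSF): over repeated stratified 10-fold
  cross-validation, scale and mRMR-rank features on each fold's training
  part only, then grow an RBF-SVM over the top-k ranked features and
  record the fold's validation AUC for every subset size k. Each
  repetition's optimal size k* is the smallest k maximising the
  fold-averaged AUC curve (averaging removes the fold-level ties that
  would otherwise collapse k* to the start of the AUC plateau); every
  fold of that repetition then contributes one selection event -- the
  top k* features of its own ranking. Aggregated counts over all
  repeats x folds events (default 200) give per-feature selection
  frequencies; features with frequency strictly above 50% survive.
* :func:`nm_dual_filter` (neuropsychological measures): a dual-ranking
  filter that keeps features whose mutual-information relevance with the
  label and whose single-feature cross-validated SVM AUC both exceed
  thresholds (defaults 0.3 bits and 0.95).

All splits, ranking and scaling touch only the training part of each
split, so no validation information leaks into the selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold
from sklearn.svm import SVC

from .mrmr import (
    DEFAULT_RULE,
    DiscretizationRule,
    _greedy_order,
    _mi_columns_vs_vector,
    discretize_matrix,
)
from .preprocessing import scale_with_bounds

__all__ = [
    "SelectionResult",
    "DualRankResult",
    "wrapper_select",
    "apply_frequency_threshold",
    "single_feature_cv_auc",
    "nm_dual_filter",
]


@dataclass
class SelectionResult:
    """Per-feature selection counts over resampling runs."""

    feature_names: tuple
    counts: np.ndarray  # int, per feature
    total_runs: int  # repeats * folds
    run_subset_sizes: list  # chosen k* per run
    seed: int

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / float(self.total_runs)

    def to_dict(self) -> dict:
        return {
            "total_runs": self.total_runs,
            "seed": self.seed,
            "run_subset_sizes": [int(s) for s in self.run_subset_sizes],
            "features": [
                {"name": n, "count": int(c), "frequency": float(c) / self.total_runs}
                for n, c in zip(self.feature_names, self.counts)
            ],
        }


@dataclass
class DualRankResult:
    """Dual ranking (MI relevance and single-feature AUC) with pass flags."""

    feature_names: tuple
    relevance: np.ndarray  # mean MI with label over splits, bits
    auc: np.ndarray  # mean single-feature validation AUC
    relevance_rank: np.ndarray  # 1-based, by descending relevance
    auc_rank: np.ndarray  # 1-based, by descending AUC
    passed: np.ndarray  # bool
    rel_threshold: float
    auc_threshold: float

    @property
    def selected(self) -> list:
        order = np.argsort(-self.relevance, kind="stable")
        return [self.feature_names[j] for j in order if self.passed[j]]

    def to_dict(self) -> dict:
        return {
            "rel_threshold": self.rel_threshold,
            "auc_threshold": self.auc_threshold,
            "features": [
                {
                    "name": n,
                    "relevance": float(r),
                    "auc": float(a),
                    "relevance_rank": int(rr),
                    "auc_rank": int(ar),
                    "passed": bool(p),
                }
                for n, r, a, rr, ar, p in zip(
                    self.feature_names,
                    self.relevance,
                    self.auc,
                    self.relevance_rank,
                    self.auc_rank,
                    self.passed,
                )
            ],
        }


def _prepare_xy(X, y):
    if isinstance(X, pd.DataFrame):
        names = tuple(X.columns)
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValueError("expected a 2-D feature matrix")
        names = tuple(f"f{i}" for i in range(arr.shape[1]))
    classes, y01 = np.unique(np.asarray(y), return_inverse=True)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    if np.isnan(arr).any():
        raise ValueError("missing values are not supported")
    return arr, names, y01.astype(np.int64)


def _splits(y01, repeats, folds, seed):
    counts = np.bincount(y01)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} subjects; cannot stratify into {folds} folds"
        )
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    return cv.split(np.zeros(len(y01)), y01)


def _fold_auc(y_true01, scores) -> float:
    return float(roc_auc_score(y_true01, scores))


def wrapper_select(
    X,
    y,
    *,
    repeats: int = 20,
    folds: int = 10,
    max_subset_size: int | None = 30,
    scheme: str = "MID",
    wrapper_C: float = 1.0,
    wrapper_gamma: float = 2.0,
    rule: DiscretizationRule = DEFAULT_RULE,
    seed: int = 0,
) -> SelectionResult:
    """mRMR + incremental-SVM wrapper with repeated CV.

    ``X`` holds the NC and AD subjects (rows) of one modality, ``y``
    their binary labels. The wrapper-stage SVM uses fixed
    hyperparameters: C = ``wrapper_C`` and a fixed RBF width
    ``wrapper_gamma`` on the [0, 1]-scaled features, so that adding
    uninformative features measurably dilutes the kernel and the
    incremental AUC curve has an interior maximum (with a width scaled
    by 1/k extra features are nearly free and subset sizing is
    ill-posed). Hyperparameter tuning happens only in the final
    classifier. Deterministic given ``seed``.
    """
    arr, names, y01 = _prepare_xy(X, y)
    counts_ok = np.bincount(y01)
    if counts_ok.min() < folds:
        raise ValueError(
            f"smallest class has {counts_ok.min()} subjects; cannot stratify into {folds} folds"
        )
    p = arr.shape[1]
    K = p if max_subset_size is None else min(p, int(max_subset_size))
    counts = np.zeros(p, dtype=np.int64)
    sizes = []
    rep_seeds = [
        int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(repeats)
    ]
    for rep in range(repeats):
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rep_seeds[rep])
        fold_orders = []
        fold_aucs = np.empty((folds, K))
        for fi, (train_idx, val_idx) in enumerate(cv.split(arr, y01)):
            Xtr, Xval = arr[train_idx], arr[val_idx]
            ytr, yval = y01[train_idx], y01[val_idx]
            mins, maxs = Xtr.min(axis=0), Xtr.max(axis=0)
            Str = scale_with_bounds(Xtr, mins, maxs)
            Sval = scale_with_bounds(Xval, mins, maxs)
            Xd = discretize_matrix(Str, rule)
            relevance = _mi_columns_vs_vector(Xd, ytr)
            order, _ = _greedy_order(Xd, relevance, scheme, K)
            fold_orders.append(order)
            for k in range(1, K + 1):
                cols = order[:k]
                svc = SVC(C=wrapper_C, kernel="rbf", gamma=wrapper_gamma)
                svc.fit(Str[:, cols], ytr)
                fold_aucs[fi, k - 1] = _fold_auc(yval, svc.decision_function(Sval[:, cols]))
        # smallest k at the maximum of the fold-averaged AUC curve
        k_star = int(np.argmax(fold_aucs.mean(axis=0))) + 1
        for order in fold_orders:
            counts[order[:k_star]] += 1
            sizes.append(k_star)
    return SelectionResult(names, counts, len(sizes), sizes, seed)


def apply_frequency_threshold(result: SelectionResult, threshold: float = 0.50) -> list:
    """Features with selection frequency strictly above ``threshold``,
    ordered by descending frequency (stable for ties)."""
    freq = result.frequencies
    order = np.argsort(-freq, kind="stable")
    return [result.feature_names[j] for j in order if freq[j] > threshold]


def single_feature_cv_auc(
    feature,
    y,
    *,
    repeats: int = 20,
    folds: int = 10,
    wrapper_C: float = 1.0,
    seed: int = 0,
) -> float:
    """Mean validation AUC of an RBF-SVM trained on one scaled feature.

    The AUC is computed on decision values, so a feature that decreases
    with the positive class scores just as well as one that increases.
    """
    x = np.asarray(feature, dtype=float).reshape(-1, 1)
    arr, _, y01 = _prepare_xy(x, y)
    aucs = []
    for train_idx, val_idx in _splits(y01, repeats, folds, seed):
        Xtr, Xval = arr[train_idx], arr[val_idx]
        mins, maxs = Xtr.min(axis=0), Xtr.max(axis=0)
        if (maxs == mins).all():
            aucs.append(0.5)
            continue
        svc = SVC(C=wrapper_C, kernel="rbf", gamma="auto")
        svc.fit(scale_with_bounds(Xtr, mins, maxs), y01[train_idx])
        scores = svc.decision_function(scale_with_bounds(Xval, mins, maxs))
        if np.ptp(scores) == 0:
            aucs.append(0.5)
        else:
            aucs.append(_fold_auc(y01[val_idx], scores))
    return float(np.mean(aucs))


def nm_dual_filter(
    X,
    y,
    *,
    rel_threshold: float = 0.3,
    auc_threshold: float = 0.95,
    repeats: int = 20,
    folds: int = 10,
    wrapper_C: float = 1.0,
    rule: DiscretizationRule = DEFAULT_RULE,
    seed: int = 0,
) -> DualRankResult:
    """Dual-ranking filter for neuropsychological measures.

    Relevance is the MI between each (scaled, discretised) feature and
    the label, averaged over the training parts of the same resampling
    splits used for the AUC ranking; a feature passes only if both
    thresholds are strictly exceeded.
    """
    arr, names, y01 = _prepare_xy(X, y)
    p = arr.shape[1]
    if p == 0:
        raise ValueError("empty feature list")
    rel_sum = np.zeros(p)
    auc_sum = np.zeros(p)
    n_splits = 0
    for train_idx, val_idx in _splits(y01, repeats, folds, seed):
        Xtr, Xval = arr[train_idx], arr[val_idx]
        ytr, yval = y01[train_idx], y01[val_idx]
        mins, maxs = Xtr.min(axis=0), Xtr.max(axis=0)
        Str = scale_with_bounds(Xtr, mins, maxs)
        Sval = scale_with_bounds(Xval, mins, maxs)
        rel_sum += _mi_columns_vs_vector(discretize_matrix(Str, rule), ytr)
        for j in range(p):
            if maxs[j] == mins[j]:
                auc_sum[j] += 0.5
                continue
            svc = SVC(C=wrapper_C, kernel="rbf", gamma="auto")
            svc.fit(Str[:, j : j + 1], ytr)
            scores = svc.decision_function(Sval[:, j : j + 1])
            auc_sum[j] += 0.5 if np.ptp(scores) == 0 else _fold_auc(yval, scores)
        n_splits += 1
    relevance = rel_sum / n_splits
    auc = auc_sum / n_splits
    rel_rank = np.empty(p, dtype=np.int64)
    rel_rank[np.argsort(-relevance, kind="stable")] = np.arange(1, p + 1)
    auc_rank = np.empty(p, dtype=np.int64)
    auc_rank[np.argsort(-auc, kind="stable")] = np.arange(1, p + 1)
    passed = (relevance > rel_threshold) & (auc > auc_threshold)
    return DualRankResult(
        names, relevance, auc, rel_rank, auc_rank, passed, rel_threshold, auc_threshold
    )
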