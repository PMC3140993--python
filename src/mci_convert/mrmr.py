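"""Mutual information and minimum-redundancy / maximum-relevance ranking.

Continuous features are discretised into three states (low / mid / high)
around their mean: values below mu - k*sigma are "low", above mu + k*sigma
"high", and "mid" otherwise (boundaries inclusive to mid). Mutual
information is the plug-in estimate, in bits, from empirical joint
frequencies. Ranking is greedy forward selection: the first feature
maximises relevance I(f; label); each subsequent feature maximises

* MID:  relevance - mean MI with the already-selected features,
* MIQ:  relevance / mean MI with the already-selected features,
* maxrel: relevance alone (redundancy ignored).

Ties are broken by original column order, making the ranking
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DiscretizationRule",
    "RankedFeature",
    "RankedFeatureList",
    "discretize",
    "discretize_matrix",
    "mutual_information",
    "mrmr_rank",
]

_SCHEMES = ("MID", "MIQ", "maxrel")


@dataclass(frozen=True)
class DiscretizationRule:
    """Three-state discretisation at mean +/- multiplier * SD (sample SD)."""

    scheme: str = "mean_sigma_3state"
    sigma_multiplier: float = 1.0

    def __post_init__(self):
        if self.scheme != "mean_sigma_3state":
            raise ValueError(f"unknown discretisation scheme {self.scheme!r}")
        if self.sigma_multiplier <= 0:
            raise ValueError("sigma_multiplier must be > 0")


DEFAULT_RULE = DiscretizationRule()


def discretize(values, rule: DiscretizationRule = DEFAULT_RULE) -> np.ndarray:
    """Map a real vector to {0, 1, 2} = {low, mid, high}.

    A zero-variance vector is entirely "mid".
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D vector with at least 2 values")
    return discretize_matrix(x[:, None], rule)[:, 0]


def discretize_matrix(X, rule: DiscretizationRule = DEFAULT_RULE) -> np.ndarray:
    """Column-wise three-state discretisation of a 2-D matrix."""
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    mu = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(arr.shape[1])
    k = rule.sigma_multiplier
    out = np.ones(arr.shape, dtype=np.int8)  # mid
    with np.errstate(invalid="ignore"):
        lo = arr < mu - k * sd
        hi = arr > mu + k * sd
    nz = sd > 0
    out[lo & nz] = 0
    out[hi & nz] = 2
    return out


def _codes(v) -> np.ndarray:
    """Integer codes 0..K-1 for an arbitrary categorical vector."""
    _, inv = np.unique(np.asarray(v), return_inverse=True)
    return inv.astype(np.int64)


def mutual_information(x, y) -> float:
    """Plug-in mutual information, in bits, of two categorical vectors."""
    cx, cy = _codes(x), _codes(y)
    if cx.shape != cy.shape:
        raise ValueError("vectors must have equal length")
    if cx.size == 0:
        raise ValueError("vectors must be non-empty")
    nx, ny = cx.max() + 1, cy.max() + 1
    joint = np.bincount(cx * ny + cy, minlength=nx * ny).reshape(nx, ny)
    return _mi_from_joint(joint[None, :, :])[0]


def _mi_from_joint(counts: np.ndarray) -> np.ndarray:
    """MI (bits) for a stack of joint count tables, shape (p, r, c)."""
    counts = counts.astype(float)
    n = counts.sum(axis=(1, 2), keepdims=True)
    pxy = counts / n
    px = pxy.sum(axis=2, keepdims=True)
    py = pxy.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pxy > 0, pxy / (px * py), 1.0)
        terms = np.where(pxy > 0, pxy * np.log2(ratio), 0.0)
    return terms.sum(axis=(1, 2))


def _mi_columns_vs_vector(Xd: np.ndarray, y: np.ndarray) -> np.ndarray:
    """MI (bits) of each 3-state column of ``Xd`` with binary vector ``y``."""
    n, p = Xd.shape
    offsets = 6 * np.arange(p, dtype=np.int64)
    idx = offsets[None, :] + 2 * Xd.astype(np.int64) + y[:, None]
    counts = np.bincount(idx.ravel(), minlength=6 * p).reshape(p, 3, 2)
    return _mi_from_joint(counts)


def _mi_vector_vs_columns(xd: np.ndarray, Xd: np.ndarray) -> np.ndarray:
    """MI (bits) of one 3-state vector with each 3-state column of ``Xd``."""
    n, p = Xd.shape
    offsets = 9 * np.arange(p, dtype=np.int64)
    idx = offsets[None, :] + 3 * xd.astype(np.int64)[:, None] + Xd.astype(np.int64)
    counts = np.bincount(idx.ravel(), minlength=9 * p).reshape(p, 3, 3)
    return _mi_from_joint(counts)


@dataclass(frozen=True)
class RankedFeature:
    name: str
    relevance: float  # MI with the class label, bits
    score: float  # value of the greedy criterion when chosen
    rank: int  # 1-based


class RankedFeatureList:
    """Ordered ranking; iterable of :class:`RankedFeature`."""

    def __init__(self, entries):
        self.entries = list(entries)

    @property
    def names(self):
        return [e.name for e in self.entries]

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, i):
        return self.entries[i]


def mrmr_rank(
    features,
    labels,
    scheme: str = "MID",
    k: int | None = None,
    rule: DiscretizationRule = DEFAULT_RULE,
    feature_names=None,
) -> RankedFeatureList:
    """Rank features against a binary label.

    ``features`` may be a DataFrame or an ndarray of raw (continuous)
    values; they are discretised internally with ``rule``. ``k`` limits
    the number of ranked entries returned (greedy search stops there).
    """
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; use one of {_SCHEMES}")
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        arr = features.to_numpy(dtype=float)
    else:
        arr = np.asarray(features, dtype=float)
        if arr.ndim != 2:
            raise ValueError("expected a 2-D feature matrix")
        names = list(feature_names) if feature_names is not None else [
            f"f{i}" for i in range(arr.shape[1])
        ]
    y = _codes(labels)
    if y.max() > 1:
        raise ValueError("labels must be binary")
    if y.shape[0] != arr.shape[0]:
        raise ValueError("labels length must match number of rows")
    p = arr.shape[1]
    if k is None:
        k = p
    if not 1 <= k <= p:
        raise ValueError(f"k must be in [1, {p}]")

    Xd = discretize_matrix(arr, rule)
    relevance = _mi_columns_vs_vector(Xd, y)
    order, scores = _greedy_order(Xd, relevance, scheme, k)
    entries = [
        RankedFeature(names[j], float(relevance[j]), float(scores[i]), i + 1)
        for i, j in enumerate(order)
    ]
    return RankedFeatureList(entries)


def _greedy_order(Xd, relevance, scheme, k):
    """Greedy mRMR order over discretised columns; returns (order, scores)."""
    p = Xd.shape[1]
    if scheme == "maxrel":
        order = np.argsort(-relevance, kind="stable")[:k]
        return order, relevance[order]
    selected = np.zeros(p, dtype=bool)
    red_sum = np.zeros(p)
    order, scores = [], []
    j = int(np.argmax(relevance))  # ties -> lowest column index
    for step in range(k):
        if step > 0:
            red_mean = red_sum / step
            if scheme == "MID":
                crit = relevance - red_mean
            else:  # MIQ
                crit = relevance / np.maximum(red_mean, 1e-12)
            crit = np.where(selected, -np.inf, crit)
            j = int(np.argmax(crit))
            scores.append(crit[j])
        else:
            scores.append(relevance[j])
        selected[j] = True
        order.append(j)
        if step + 1 < k:
            red_sum += _mi_vector_vs_columns(Xd[:, j], Xd)
    return np.asarray(order), np.asarray(scores)
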