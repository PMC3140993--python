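"""Independent brute-force oracles used only by the test suite.

Each function re-derives a quantity by the most direct (usually O(n^2)
or exhaustive) route, sharing no code with the implementation paths it
checks.
"""

import math
from collections import Counter

import numpy as np


def mi_bits(x, y) -> float:
    """Plug-in mutual information by explicit summation over value pairs."""
    x = list(x)
    y = list(y)
    n = len(x)
    joint = Counter(zip(x, y))
    px = Counter(x)
    py = Counter(y)
    total = 0.0
    for (a, b), c in joint.items():
        pxy = c / n
        total += pxy * math.log2(pxy / ((px[a] / n) * (py[b] / n)))
    return total


def entropy_bits(x) -> float:
    n = len(list(x))
    return -sum((c / n) * math.log2(c / n) for c in Counter(x).values())


def greedy_mrmr_order(Xd, y, scheme="MID"):
    """Greedy mRMR re-evaluation with plain loops over discretised columns."""
    p = Xd.shape[1]
    relevance = [mi_bits(Xd[:, j], y) for j in range(p)]
    if scheme == "maxrel":
        return sorted(range(p), key=lambda j: (-relevance[j], j))
    order = [max(range(p), key=lambda j: (relevance[j], -j))]
    while len(order) < p:
        best, best_score = None, None
        for j in range(p):
            if j in order:
                continue
            red = sum(mi_bits(Xd[:, j], Xd[:, s]) for s in order) / len(order)
            if scheme == "MID":
                score = relevance[j] - red
            else:  # MIQ
                score = relevance[j] / max(red, 1e-12)
            if best_score is None or score > best_score:
                best, best_score = j, score
        order.append(best)
    return order


def pair_count_auc(scores, positive_mask) -> float:
    """AUC by exhaustive positive/negative pair comparison (ties = 1/2)."""
    scores = np.asarray(scores, dtype=float)
    positive_mask = np.asarray(positive_mask, dtype=bool)
    pos = scores[positive_mask]
    neg = scores[~positive_mask]
    total = 0.0
    for s_pos in pos:
        for s_neg in neg:
            if s_pos > s_neg:
                total += 1.0
            elif s_pos == s_neg:
                total += 0.5
    return total / (len(pos) * len(neg))


def chi2_expected_counts(a, b, c, d) -> float:
    """Pearson chi-square via the sum over cells of (O - E)^2 / E."""
    table = np.array([[a, b], [c, d]], dtype=float)
    n = table.sum()
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / n
            stat += (table[i, j] - e) ** 2 / e
    return stat
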