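"""Independent brute-force oracles used to check the metric implementations.

Everything here works by direct enumeration over cell pairs or label
counts, deliberately avoiding the contingency-table formulas used by the
package.
"""

from __future__ import annotations

from collections import Counter
from itertools import combinations
from math import log, sqrt


def pair_counts(truth, pred):
    """(a, b, c, d): together-in-both, truth-only, pred-only, neither."""
    a = b = c = d = 0
    for i, j in combinations(range(len(truth)), 2):
        same_t = truth[i] == truth[j]
        same_p = pred[i] == pred[j]
        if same_t and same_p:
            a += 1
        elif same_t:
            b += 1
        elif same_p:
            c += 1
        else:
            d += 1
    return a, b, c, d


def ari_oracle(truth, pred):
    """ARI via the pair-count identity 2(ad - bc)/((a+b)(b+d)+(a+c)(c+d))."""
    a, b, c, d = pair_counts(truth, pred)
    denom = (a + b) * (b + d) + (a + c) * (c + d)
    if denom == 0:
        return 1.0 if (b == 0 and c == 0) else 0.0
    return 2.0 * (a * d - b * c) / denom


def fmi_oracle(truth, pred):
    a, b, c, _ = pair_counts(truth, pred)
    if a == 0:
        return 0.0
    return a / sqrt((a + b) * (a + c))


def _entropy(labels):
    n = len(labels)
    return -sum(k / n * log(k / n) for k in Counter(labels).values())


def v_measure_oracle(truth, pred):
    """V-measure from conditional entropies computed on raw label lists."""
    n = len(truth)
    h_c, h_k = _entropy(truth), _entropy(pred)
    joint = Counter(zip(truth, pred))
    pred_counts = Counter(pred)
    true_counts = Counter(truth)
    h_c_given_k = -sum(v / n * log(v / pred_counts[p]) for (_t, p), v in joint.items())
    h_k_given_c = -sum(v / n * log(v / true_counts[t]) for (t, _p), v in joint.items())
    hom = 1.0 if h_c == 0 else 1.0 - h_c_given_k / h_c
    comp = 1.0 if h_k == 0 else 1.0 - h_k_given_c / h_k
    if hom + comp == 0:
        return 0.0
    return 2 * hom * comp / (hom + comp)


def roc_area_oracle(scores, truth):
    """Probability a positive outscores a negative, ties counting half."""
    pos = [s for s, t in zip(scores, truth) if t]
    neg = [s for s, t in zip(scores, truth) if not t]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def all_partitions(n):
    """All set partitions of range(n) as label tuples (restricted growth)."""
    def grow(prefix, k):
        if len(prefix) == n:
            yield tuple(prefix)
            return
        for v in range(k + 1):
            yield from grow(prefix + [v], max(k, v + 1))
    yield from grow([0], 1)
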