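"""Evaluation measures for classifications, clusterings and embeddings.

All external indices (weighted F-score, adjusted Rand index, Fowlkes-Mallows
index, V-measure) are computed from an explicit true-by-predicted
contingency table; embedding quality is scored by the neighborhood
proportion error (NPE) and residual variance; classifier quality by the
one-vs-rest ROC area.  Implementations follow the defining formulas rather
than delegating to library routines, so they can be cross-checked against
independent oracles.

Conventions adopted for degenerate inputs are documented per function.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy.stats import rankdata
from sklearn.neighbors import NearestNeighbors


@dataclass(frozen=True)
class ContingencyTable:
    """Integer cross-tabulation N_ij of true class i versus predicted cluster j."""

    counts: np.ndarray
    true_names: list
    pred_names: list

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (len(self.true_names), len(self.pred_names)):
            raise ValueError("counts shape incompatible with label names")

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def class_confusion(self, i: int, j: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) treating true class i / predicted cluster j as positive."""
        tp = int(self.counts[i, j])
        fp = int(self.col_sums[j]) - tp
        fn = int(self.row_sums[i]) - tp
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn


def contingency(true_labels, pred_labels, exclude=()) -> ContingencyTable:
    """Cross-tabulate two label sequences of equal length.

    ``exclude`` drops cells whose *true* label is in the given set (used to
    ignore ungated cells when scoring against a partial ground truth).
    """
    true_arr = np.asarray(getattr(true_labels, "labels", true_labels), dtype=object)
    pred_arr = np.asarray(pred_labels, dtype=object)
    if len(true_arr) != len(pred_arr):
        raise ValueError(f"length mismatch: {len(true_arr)} true vs {len(pred_arr)} predicted")
    if exclude:
        keep = ~np.isin(true_arr.astype(str), [str(e) for e in exclude])
        true_arr, pred_arr = true_arr[keep], pred_arr[keep]
    if len(true_arr) == 0:
        raise ValueError("empty input: no cells to cross-tabulate")
    true_names, ti = np.unique(true_arr.astype(str), return_inverse=True)
    pred_names, pi = np.unique(pred_arr.astype(str), return_inverse=True)
    counts = np.zeros((len(true_names), len(pred_names)), dtype=np.int64)
    np.add.at(counts, (ti, pi), 1)
    return ContingencyTable(counts, list(true_names), list(pred_names))


def f_score(table: ContingencyTable) -> tuple[float, dict]:
    """Class-size-weighted F-score, F = sum_i (C_i / N) F_i.

    Predicted clusters are matched to true classes by maximum overlap
    (majority vote, many-to-one), so unsupervised clusterings can be scored
    against gated truth; per-class F_i is the usual harmonic mean
    2PR/(P+R), defined as 0 when P + R = 0.
    """
    counts = table.counts
    n_true, n_pred = counts.shape
    owner = np.argmax(counts, axis=0)  # cluster j -> majority true class
    per_class = {}
    total_f = 0.0
    for i, name in enumerate(table.true_names):
        support = int(table.row_sums[i])
        pred_mask = owner == i
        tp = int(counts[i, pred_mask].sum())
        predicted_i = int(table.col_sums[pred_mask].sum())
        precision = tp / predicted_i if predicted_i else 0.0
        recall = tp / support if support else 0.0
        fi = (2 * precision * recall / (precision + recall)
              if precision + recall > 0 else 0.0)
        per_class[name] = fi
        total_f += support / table.total * fi
    return total_f, per_class


def ari(table: ContingencyTable) -> float:
    """Adjusted Rand index from pair counts over the contingency table.

    Degenerate case (expected index equals maximum index, e.g. both
    partitions a single cluster or both all singletons): 1 when the
    partitions are identical, else 0.
    """
    n = table.total
    if n < 2:
        raise ValueError("ARI requires at least 2 cells")
    sum_ij = sum(comb(int(v), 2) for v in table.counts.ravel())
    sum_i = sum(comb(int(v), 2) for v in table.row_sums)
    sum_j = sum(comb(int(v), 2) for v in table.col_sums)
    pairs = comb(n, 2)
    expected = sum_i * sum_j / pairs
    maximum = (sum_i + sum_j) / 2
    if maximum == expected:
        identical = (sorted(table.row_sums) == sorted(table.col_sums)
                     and sum_ij == sum_i == sum_j)
        return 1.0 if identical else 0.0
    return (sum_ij - expected) / (maximum - expected)


def fmi(table: ContingencyTable) -> float:
    """Fowlkes-Mallows index: sqrt(pairwise precision x pairwise recall).

    Pair-level TP counts cell pairs placed together in both partitions; FP
    pairs together only in the prediction; FN only in the truth.  0 when
    TP = 0.
    """
    if table.total < 2:
        raise ValueError("FMI requires at least 2 cells")
    tp = sum(comb(int(v), 2) for v in table.counts.ravel())
    fp = sum(comb(int(v), 2) for v in table.col_sums) - tp
    fn = sum(comb(int(v), 2) for v in table.row_sums) - tp
    if tp == 0:
        return 0.0
    return float(np.sqrt((tp / (tp + fp)) * (tp / (tp + fn))))


def _entropy(freq: np.ndarray, n: int) -> float:
    p = freq[freq > 0] / n
    return float(-(p * np.log(p)).sum())


def v_measure(table: ContingencyTable) -> tuple[float, float, float]:
    """(v, homogeneity, completeness) from conditional entropies.

    homogeneity = 1 - H(C|K)/H(C); completeness = 1 - H(K|C)/H(K); each is 1
    when the normalising entropy is 0; v is their harmonic mean (0 if both 0).
    """
    n = table.total
    h_c = _entropy(table.row_sums, n)
    h_k = _entropy(table.col_sums, n)
    counts = table.counts
    nz = counts > 0
    p = counts[nz] / n
    col = np.broadcast_to(table.col_sums, counts.shape)[nz]
    row = np.broadcast_to(table.row_sums[:, None], counts.shape)[nz]
    h_c_given_k = float(-(p * np.log(counts[nz] / col)).sum())
    h_k_given_c = float(-(p * np.log(counts[nz] / row)).sum())
    homogeneity = 1.0 if h_c == 0 else 1.0 - h_c_given_k / h_c
    completeness = 1.0 if h_k == 0 else 1.0 - h_k_given_c / h_k
    if homogeneity + completeness == 0:
        return 0.0, homogeneity, completeness
    v = 2 * homogeneity * completeness / (homogeneity + completeness)
    return v, homogeneity, completeness


def _same_label_neighbor_fraction(X: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    neighbor_labels = labels[idx[:, 1:]]  # drop self
    return (neighbor_labels == labels[:, None]).mean(axis=1)


def npe(original, embedded, labels, k: int = 20) -> float:
    """Neighborhood proportion error between original and embedded space.

    For each cell, the fraction of its k nearest neighbors sharing its
    subtype is computed in both spaces; per subtype the two empirical
    distributions of that fraction (support {0, 1/k, ..., 1}) are compared
    by total-variation distance, and the per-cell average of the subtype
    distances is returned.  0 means neighborhoods are perfectly preserved.
    Subtypes with fewer than 2 cells are skipped with a warning.
    """
    X = np.asarray(getattr(original, "values", original), dtype=float)
    Y = np.asarray(getattr(embedded, "coords", embedded), dtype=float)
    lab = np.asarray(getattr(labels, "labels", labels), dtype=object)
    if not len(X) == len(Y) == len(lab):
        raise ValueError("original, embedding and labels must cover the same cells")
    if k >= len(X):
        raise ValueError("k must be smaller than the number of cells")
    frac_orig = _same_label_neighbor_fraction(X, lab, k)
    frac_emb = _same_label_neighbor_fraction(Y, lab, k)
    total, n_scored = 0.0, 0
    for subtype in np.unique(lab.astype(str)):
        members = np.flatnonzero(lab.astype(str) == subtype)
        if len(members) < 2:
            warnings.warn(f"subtype {subtype!r} has < 2 cells; skipped in NPE")
            continue
        p = np.histogram(frac_orig[members], bins=k + 1,
                         range=(-0.5 / k, 1 + 0.5 / k))[0] / len(members)
        q = np.histogram(frac_emb[members], bins=k + 1,
                         range=(-0.5 / k, 1 + 0.5 / k))[0] / len(members)
        delta = 0.5 * np.abs(p - q).sum()
        total += delta * len(members)
        n_scored += len(members)
    return total / n_scored if n_scored else 0.0


def residual_variance(original_distances, embedded_distances) -> float:
    """1 - R^2 between matched distance vectors; 1 when either is constant."""
    d_g = np.asarray(original_distances, dtype=float).ravel()
    d_y = np.asarray(embedded_distances, dtype=float).ravel()
    if d_g.shape != d_y.shape:
        raise ValueError("distance vectors must have matching shapes")
    if d_g.std() == 0 or d_y.std() == 0:
        return 1.0
    r = np.corrcoef(d_g, d_y)[0, 1]
    return float(1.0 - r**2)


def roc_curve_area(scores, truth) -> float:
    """Area under the ROC curve via the rank statistic (ties count 1/2).

    Equivalent to the trapezoidal area of TPR against FPR over all score
    thresholds.  Errors if either class is absent.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    n_pos = int(truth.sum())
    n_neg = len(truth) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC area undefined: one class absent")
    ranks = rankdata(scores)  # average ranks implement the tie convention
    return float((ranks[truth == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class MetricsReport:
    """All external indices for one prediction, JSON-serialisable."""

    f_score: float
    per_class_f: dict
    ari: float
    fmi: float
    v_measure: float
    homogeneity: float
    completeness: float
    npe: float | None = None
    residual_variance: float | None = None
    roc_areas: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.__dict__, indent=1, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def format_table(self) -> str:
        rows = [("F-score", self.f_score), ("ARI", self.ari), ("FMI", self.fmi),
                ("V-measure", self.v_measure)]
        if self.npe is not None:
            rows.append(("NPE", self.npe))
        if self.residual_variance is not None:
            rows.append(("Residual variance", self.residual_variance))
        width = max(len(name) for name, _ in rows)
        return "\n".join(f"{name:<{width}}  {value:.4f}" for name, value in rows)


def score_prediction(true_labels, pred_labels, exclude=()) -> MetricsReport:
    """Convenience wrapper computing every contingency-based index at once."""
    table = contingency(true_labels, pred_labels, exclude=exclude)
    f, per_class = f_score(table)
    v, hom, comp = v_measure(table)
    return MetricsReport(
        f_score=f, per_class_f=per_class, ari=ari(table), fmi=fmi(table),
        v_measure=v, homogeneity=hom, completeness=comp,
    )
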