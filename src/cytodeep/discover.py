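"""Novel-population discovery: fuzzy-neighbor embedding + density clustering.

Residual unknown cells are embedded into 2-3 dimensions by UMAP and
clustered there with HDBSCAN's condensed-tree stability selection; each
stable cluster becomes a candidate new population and unclaimed cells stay
noise.  The fuzzy k-neighbor graph underlying the embedding (directed
weights w_i(x_i, x_j) = exp(-(d - rho_i)/sigma_i), symmetrised as
A = w_i + w_j - w_i * w_j) and the mutual-reachability distance
max{core_k(a), core_k(b), d(a, b)} are implemented here from the formulas;
the embedding optimiser and the condensed-tree extraction are delegated to
umap-learn and scikit-learn behind those contracts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import HDBSCAN
from sklearn.neighbors import NearestNeighbors

from .calibrate import SOURCE_NOISE, SOURCE_NOVEL, ClusterAssignment
from .io import NOISE, MarkerTable

DEFAULT_K = 20  # neighbor count used throughout the evaluation setting
SMOOTH_K_TOLERANCE = 1e-5


@dataclass(frozen=True)
class NeighborGraph:
    """Directed fuzzy k-NN graph and its symmetrised adjacency."""

    k: int
    indices: np.ndarray        # (n, k) neighbor ids, nearest first
    distances: np.ndarray      # (n, k) distances to those neighbors
    rho: np.ndarray            # per-point nearest-neighbor distance
    sigma: np.ndarray          # per-point bandwidth
    weights: np.ndarray        # (n, k) directed membership weights
    adjacency: sparse.csr_matrix  # symmetric fuzzy union

    @property
    def n_cells(self) -> int:
        return len(self.rho)


@dataclass(frozen=True)
class Embedding:
    """Low-dimensional coordinates with the seed that produced them."""

    coords: np.ndarray
    seed: int = 0
    cross_entropy: float | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.size and not np.isfinite(coords).all():
            raise ValueError("embedding contains non-finite coordinates")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    @property
    def n_dim(self) -> int:
        return self.coords.shape[1]


@dataclass(frozen=True)
class DensityClustering:
    """Flat clusters extracted from the condensed density hierarchy."""

    labels: np.ndarray              # cluster id per cell, -1 = noise
    min_cluster_size: int
    cluster_sizes: dict = field(default_factory=dict)
    membership_strength: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)


def fuzzy_union(w_directed: sparse.spmatrix) -> sparse.csr_matrix:
    """Symmetrise directed weights: A = w + w^T - w o w^T (elementwise)."""
    w = sparse.csr_matrix(w_directed)
    wt = w.T.tocsr()
    return (w + wt - w.multiply(wt)).tocsr()


def _smooth_knn_sigma(dists: np.ndarray, rho: float, target: float,
                      n_iter: int = 64) -> float:
    """Binary-search sigma so sum_j exp(-(d_j - rho)/sigma) = target."""
    lo, hi, mid = 0.0, np.inf, 1.0
    shifted = np.maximum(dists - rho, 0.0)
    for _ in range(n_iter):
        mass = np.exp(-shifted / mid).sum()
        if abs(mass - target) < SMOOTH_K_TOLERANCE:
            break
        if mass > target:
            hi = mid
            mid = (lo + hi) / 2
        else:
            lo = mid
            mid = mid * 2 if np.isinf(hi) else (lo + hi) / 2
    return max(mid, 1e-12)


def build_fuzzy_graph(table: MarkerTable | np.ndarray, k: int = DEFAULT_K) -> NeighborGraph:
    """Construct the directed fuzzy k-NN graph and its symmetric adjacency.

    The per-point bandwidth sigma_i is calibrated so the total membership
    mass over the k neighbors equals log2(k) (smooth-kNN calibration); the
    nearest neighbor always receives weight exactly 1 because d = rho_i.
    """
    X = np.asarray(getattr(table, "values", table), dtype=float)
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} requires at least k+1={k + 1} cells, got {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dists, idx = nn.kneighbors(X)
    dists, idx = dists[:, 1:], idx[:, 1:]  # drop self
    rho = dists[:, 0].copy()
    target = np.log2(k)
    sigma = np.array([_smooth_knn_sigma(dists[i], rho[i], target) for i in range(n)])
    weights = np.exp(-np.maximum(dists - rho[:, None], 0.0) / sigma[:, None])
    rows = np.repeat(np.arange(n), k)
    w = sparse.csr_matrix((weights.ravel(), (rows, idx.ravel())), shape=(n, n))
    adjacency = fuzzy_union(w)
    adjacency.setdiag(0.0)
    adjacency.eliminate_zeros()
    return NeighborGraph(k=k, indices=idx, distances=dists, rho=rho, sigma=sigma,
                         weights=weights, adjacency=adjacency)


def embed(
    table: MarkerTable | np.ndarray,
    d_low: int = 2,
    k: int = DEFAULT_K,
    seed: int = 0,
    n_epochs: int | None = None,
    min_dist: float = 0.1,
) -> Embedding:
    """UMAP embedding of the cells; deterministic for a fixed seed.

    The achieved fuzzy cross-entropy between the high-dimensional graph
    weights and the low-dimensional kernel, summed over the graph's edges,
    is reported on the Embedding for diagnostics.
    """
    import umap  # deferred: numba compilation is expensive at import time

    X = np.asarray(getattr(table, "values", table), dtype=float)
    if d_low not in (2, 3):
        raise ValueError("d_low must be 2 or 3")
    k = min(k, X.shape[0] - 1)
    reducer = umap.UMAP(n_neighbors=k, n_components=d_low, random_state=seed,
                        n_epochs=n_epochs, min_dist=min_dist)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns that random_state forces 1 thread
        coords = reducer.fit_transform(X)
    if not np.isfinite(coords).all():
        raise RuntimeError("embedding produced non-finite coordinates")
    ce = _edge_cross_entropy(build_fuzzy_graph(X, k=k), coords,
                             a=float(reducer._a), b=float(reducer._b))
    return Embedding(coords=np.asarray(coords, dtype=float), seed=seed,
                     cross_entropy=ce)


def _edge_cross_entropy(graph: NeighborGraph, coords: np.ndarray,
                        a: float, b: float) -> float:
    """Fuzzy cross-entropy C(w, w') over the high-dimensional graph edges,
    with w'(i,j) = (1 + a * |y_i - y_j|^(2b))^-1."""
    coords = np.asarray(coords, dtype=np.float64)  # float32 would round w' to 1
    A = sparse.coo_matrix(sparse.triu(graph.adjacency))
    d2 = ((coords[A.row] - coords[A.col]) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", over="ignore"):
        w_low = 1.0 / (1.0 + a * d2**b)
    w = np.clip(A.data, 1e-9, 1 - 1e-9)
    w_low = np.clip(w_low, 1e-9, 1 - 1e-9)
    ce = w * np.log(w / w_low) + (1 - w) * np.log((1 - w) / (1 - w_low))
    return float(ce.sum())


def mutual_reachability(distances: np.ndarray, core_k: int) -> np.ndarray:
    """Mutual-reachability matrix: max{core_k(a), core_k(b), d(a, b)}.

    ``distances`` is a square matrix; core_k(x) is the distance from x to
    its core_k-th nearest other point.  The diagonal is 0 by convention.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distances must be a square matrix")
    n = d.shape[0]
    if not 1 <= core_k <= n - 1:
        raise ValueError(f"core_k must be in [1, {n - 1}]")
    sorted_rows = np.sort(d + np.diag(np.full(n, np.inf)), axis=1)
    core = sorted_rows[:, core_k - 1]
    m = np.maximum(d, np.maximum(core[:, None], core[None, :]))
    np.fill_diagonal(m, 0.0)
    return m


def auto_selection_epsilon(coords: np.ndarray, k: int) -> float:
    """Density cut for cluster extraction: 95th percentile of k-NN distance.

    Merging hierarchy levels below this scale keeps each population's
    internal density fluctuations from surfacing as separate clusters and
    lets a pool dominated by one single novel population be extracted as
    one cluster (with root selection enabled) instead of dissolving into
    noise.  Well-separated populations sit farther apart than this scale,
    so distinct populations are not merged.
    """
    coords = np.asarray(coords, dtype=float)
    k = min(k, coords.shape[0] - 1)
    if k < 1:
        return 0.0
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    dists, _ = nn.kneighbors(coords)
    return float(np.percentile(dists[:, -1], 95))


def default_min_cluster_size(n_cells: int) -> int:
    """max(15, 2% of the cells) — scales with the unknown pool.

    The floor of 2% reflects how the unknown pool is built upstream: the
    confidence filter rejects the bottom few percent of every canonical
    population, and the cells of that tail which the feedback calibration
    does not reclaim sit in the pool as one tight clump per canonical
    population, each typically around 1% of the pool.  A minimum cluster
    size above that contamination scale keeps those clumps out of the
    reported novel populations (they fall to noise) while any genuinely
    novel population of practical interest remains far larger.
    """
    return max(15, int(round(0.02 * n_cells)))


def cluster_unknown(embedding: Embedding | np.ndarray,
                    min_cluster_size: int | None = None,
                    allow_single_cluster: bool = False,
                    cluster_selection_epsilon: float = 0.0) -> DensityClustering:
    """Extract stable density clusters from the embedding; the rest is noise.

    Cluster ids are relabeled by decreasing cluster size (0 = largest).
    With fewer cells than ``min_cluster_size`` everything is noise.  The
    default excess-of-mass extraction never selects the hierarchy's root,
    so a pool consisting of one single homogeneous population comes back as
    noise; for that regime pass ``allow_single_cluster=True`` together with
    a density cut ``cluster_selection_epsilon`` (e.g. a high percentile of
    the k-nearest-neighbor distances).
    """
    coords = np.asarray(getattr(embedding, "coords", embedding), dtype=float)
    n = coords.shape[0]
    if min_cluster_size is None:
        min_cluster_size = default_min_cluster_size(n)
    if n < min_cluster_size or n < 2:
        warnings.warn(
            f"only {n} cells but min_cluster_size={min_cluster_size}; all noise"
        )
        return DensityClustering(labels=np.full(n, -1), min_cluster_size=min_cluster_size)
    model = HDBSCAN(min_cluster_size=min_cluster_size,
                    allow_single_cluster=allow_single_cluster,
                    cluster_selection_epsilon=cluster_selection_epsilon,
                    copy=True)
    raw = model.fit_predict(coords)
    ids, counts = np.unique(raw[raw >= 0], return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap.get(l, -1) for l in raw])
    sizes = {remap[i]: int(c) for i, c in zip(ids, counts)}
    strength = {
        remap[i]: float(np.mean(model.probabilities_[raw == i])) for i in ids
    }
    return DensityClustering(labels=labels, min_cluster_size=min_cluster_size,
                             cluster_sizes=dict(sorted(sizes.items())),
                             membership_strength=dict(sorted(strength.items())))


def name_novel_clusters(
    clustering: DensityClustering,
    existing_names: list[str],
    cell_ids: list[str] | None = None,
) -> ClusterAssignment:
    """Name clusters new_1..new_m by decreasing size, avoiding collisions."""
    taken = set(existing_names)
    names: dict[int, str] = {}
    counter = 1
    for cid in clustering.cluster_sizes:  # already ordered by decreasing size
        while f"new_{counter}" in taken:
            counter += 1
        names[cid] = f"new_{counter}"
        taken.add(f"new_{counter}")
    labels = np.array([names.get(l, NOISE) for l in clustering.labels], dtype=object)
    source = np.where(clustering.labels >= 0, SOURCE_NOVEL, SOURCE_NOISE).astype(object)
    if cell_ids is None:
        cell_ids = [f"cell_{i}" for i in range(len(labels))]
    return ClusterAssignment(labels=labels, source=source, cell_ids=list(cell_ids),
                             canonical_names=list(existing_names))


class NovelPopulationDiscoverer(BaseEstimator, ClusterMixin):
    """Embed-then-cluster discovery as a scikit-learn style clusterer.

    ``fit(X)`` embeds the cells with UMAP (``k`` neighbors, ``d_low``
    components) and extracts stable density clusters in the embedding.

    Attributes
    ----------
    embedding_ : Embedding of the fitted cells
    clustering_ : DensityClustering with per-cluster summaries
    labels_ : cluster id per cell, -1 for noise
    """

    def __init__(self, k=DEFAULT_K, d_low=2, min_cluster_size=None,
                 n_epochs=None, random_state=0):
        self.k = k
        self.d_low = d_low
        self.min_cluster_size = min_cluster_size
        self.n_epochs = n_epochs
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(getattr(X, "values", X), dtype=float)
        self.embedding_ = embed(X, d_low=self.d_low, k=self.k,
                                seed=self.random_state, n_epochs=self.n_epochs)
        self.clustering_ = cluster_unknown(self.embedding_, self.min_cluster_size)
        self.labels_ = self.clustering_.labels
        return self
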