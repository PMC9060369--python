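"""End-to-end orchestration: classify, filter, calibrate, discover, export.

The flow over a partially gated cohort is: train the softmax net on the
gated cells (stratified half/half train-validation split), score every
ungated cell, reject low-confidence calls into an unknown pool, run the
Spearman feedback calibration to pull misrejected canonical cells back,
embed the residual unknowns and extract stable density clusters as new
populations, then assemble a single per-cell assignment plus a 3-D view in
which the third axis is either a label index over a 2-D embedding or the
third embedding dimension.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import metrics as metrics_mod
from .calibrate import (
    DEFAULT_MAX_ITERATIONS,
    DEFAULT_SUBSAMPLE,
    SOURCE_CALIBRATED,
    SOURCE_CLASSIFIED,
    SOURCE_NOISE,
    SOURCE_NOVEL,
    UNKNOWN,
    ClusterAssignment,
    FilterConfig,
    calibrate,
    filter_low_confidence,
)
from .classify import ClassifierConfig, predict_posteriors, train
from .discover import (
    DEFAULT_K,
    Embedding,
    auto_selection_epsilon,
    cluster_unknown,
    default_min_cluster_size,
    embed,
    name_novel_clusters,
)
from .io import NOISE, UNASSIGNED, LabelVector, MarkerTable
from sklearn.base import BaseEstimator


@dataclass(frozen=True)
class CalibrationConfig:
    max_iterations: int = DEFAULT_MAX_ITERATIONS
    subsample: int = DEFAULT_SUBSAMPLE
    seed: int = 0


@dataclass(frozen=True)
class DiscoveryConfig:
    k: int = DEFAULT_K
    d_low: int = 2
    min_cluster_size: int | None = None
    n_epochs: int | None = None
    seed: int = 0
    # None -> density cut at the embedding's 95th-percentile k-NN distance,
    # with root selection allowed, so a pool dominated by a single novel
    # population is extracted as one cluster rather than dissolving
    cluster_selection_epsilon: float | None = None
    allow_single_cluster: bool = True


@dataclass(frozen=True)
class VizConfig:
    z_axis_mode: str = "label_index"  # or "third_embedding_dim"

    def __post_init__(self) -> None:
        if self.z_axis_mode not in {"label_index", "third_embedding_dim"}:
            raise ValueError(f"unknown z_axis_mode {self.z_axis_mode!r}")


@dataclass(frozen=True)
class PipelineConfig:
    """Every stage's parameters, with all seeds explicit."""

    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    discovery: DiscoveryConfig = field(default_factory=DiscoveryConfig)
    viz: VizConfig = field(default_factory=VizConfig)

    @classmethod
    def with_seed(cls, seed: int, **overrides) -> "PipelineConfig":
        """Spread a single master seed across all stages."""
        cfg = cls(
            classifier=ClassifierConfig(seed=seed),
            calibration=CalibrationConfig(seed=seed + 1),
            discovery=DiscoveryConfig(seed=seed + 2),
        )
        return replace(cfg, **overrides) if overrides else cfg


@dataclass
class RunReport:
    """Per-stage cell counts, timings and (optional) truth-based metrics.

    Conservation: classified + calibrated + novel + noise + unknown equals
    the number of ungated input cells.
    """

    n_cells: int = 0
    n_trained_on: int = 0
    n_unlabeled: int = 0
    n_classified: int = 0
    n_filtered_unknown: int = 0
    n_calibrated: int = 0
    n_novel: int = 0
    n_noise: int = 0
    n_remaining_unknown: int = 0
    novel_cluster_names: list = field(default_factory=list)
    calibration_log: list = field(default_factory=list)
    stage_seconds: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)
    metrics: dict = field(default_factory=dict)

    def check_conservation(self) -> None:
        parts = (self.n_classified + self.n_calibrated + self.n_novel
                 + self.n_noise + self.n_remaining_unknown)
        if parts != self.n_unlabeled:
            raise AssertionError(
                f"cell-count conservation violated: {parts} != {self.n_unlabeled}"
            )

    def to_dict(self) -> dict:
        return asdict(self)


def run(
    table: MarkerTable,
    labels: LabelVector,
    config: PipelineConfig | None = None,
    ground_truth: LabelVector | None = None,
) -> tuple[ClusterAssignment, Embedding, RunReport]:
    """Execute the full identification flow on a partially gated cohort.

    Returns the per-cell assignment, a full-cohort visualization embedding
    (2-D or 3-D per the viz mode), and a RunReport.  Gated cells keep their
    given labels; ungated cells end as classified, calibrated, members of a
    novel cluster, or noise.
    """
    config = config or PipelineConfig()
    if table.n_cells != labels.n_cells:
        raise ValueError("table and labels cover different numbers of cells")
    report = RunReport(n_cells=table.n_cells)
    clock = time.perf_counter

    # Step 1 - train on gated cells, score ungated cells
    t0 = clock()
    model = train(table, labels, config.classifier)
    labeled_mask = labels.labeled_mask
    report.n_trained_on = int(labeled_mask.sum())
    unlabeled_idx = np.flatnonzero(~labeled_mask)
    report.n_unlabeled = len(unlabeled_idx)
    report.stage_seconds["train"] = clock() - t0

    final_labels = np.array(labels.labels, dtype=object)
    final_source = np.full(table.n_cells, SOURCE_CLASSIFIED, dtype=object)
    canonical = [str(c) for c in model.classes_]

    remaining_unknown = np.array([], dtype=int)
    if len(unlabeled_idx):
        # Step 2 - confidence filtering of the ungated cells
        t0 = clock()
        posteriors = predict_posteriors(model, table.subset(unlabeled_idx))
        reference = predict_posteriors(model, table.subset(np.flatnonzero(labeled_mask)))
        sub_assign, sub_unknown = filter_low_confidence(
            posteriors, config.filter,
            cell_ids=[table.cell_ids[i] for i in unlabeled_idx],
            reference=reference,
        )
        final_labels[unlabeled_idx] = sub_assign.labels
        final_source[unlabeled_idx] = sub_assign.source
        unknown_idx = unlabeled_idx[sub_unknown]
        report.n_filtered_unknown = len(unknown_idx)
        report.stage_seconds["filter"] = clock() - t0

        # Step 3 - feedback calibration against canonical populations
        t0 = clock()
        assignment = ClusterAssignment(final_labels, final_source,
                                       list(table.cell_ids), canonical)
        if len(unknown_idx):
            assignment, remaining_unknown, cal_log = calibrate(
                table, assignment, unknown_idx,
                max_iterations=config.calibration.max_iterations,
                max_cells_per_population=config.calibration.subsample,
                seed=config.calibration.seed,
            )
            final_labels = assignment.labels
            final_source = assignment.source
            report.calibration_log = cal_log
        report.stage_seconds["calibrate"] = clock() - t0

        # Step 4 - embed + density-cluster the residual unknowns
        t0 = clock()
        if len(remaining_unknown):
            unknown_table = table.subset(remaining_unknown)
            disc = config.discovery
            k = min(disc.k, len(remaining_unknown) - 1)
            if k >= 1:
                discovery_embedding = embed(unknown_table, d_low=disc.d_low,
                                            k=k, seed=disc.seed,
                                            n_epochs=disc.n_epochs)
                mcs = (disc.min_cluster_size
                       or default_min_cluster_size(len(remaining_unknown)))
                eps = disc.cluster_selection_epsilon
                if eps is None:
                    eps = auto_selection_epsilon(discovery_embedding.coords, mcs)
                clustering = cluster_unknown(
                    discovery_embedding, mcs,
                    allow_single_cluster=disc.allow_single_cluster,
                    cluster_selection_epsilon=eps)
                fragment = name_novel_clusters(
                    clustering, canonical,
                    cell_ids=[table.cell_ids[i] for i in remaining_unknown],
                )
                final_labels[remaining_unknown] = fragment.labels
                final_source[remaining_unknown] = fragment.source
                report.novel_cluster_names = fragment.novel_names()
                remaining_unknown = np.array([], dtype=int)
            else:
                report.notes.append(
                    "too few residual unknown cells to embed; left unknown"
                )
        else:
            report.notes.append("no residual unknown cells; discovery skipped")
        report.stage_seconds["discover"] = clock() - t0
    else:
        report.notes.append("no ungated cells; filtering and discovery skipped")

    assignment = ClusterAssignment(final_labels, final_source,
                                   list(table.cell_ids), canonical)
    unlabeled_source = final_source[unlabeled_idx]
    report.n_classified = int(np.sum(unlabeled_source == SOURCE_CLASSIFIED))
    report.n_calibrated = int(np.sum(unlabeled_source == SOURCE_CALIBRATED))
    report.n_novel = int(np.sum(unlabeled_source == SOURCE_NOVEL))
    report.n_noise = int(np.sum(unlabeled_source == SOURCE_NOISE))
    report.n_remaining_unknown = int(np.sum(unlabeled_source == UNKNOWN))
    report.check_conservation()

    # Step 5 - full-cohort visualization embedding
    t0 = clock()
    d_view = 3 if config.viz.z_axis_mode == "third_embedding_dim" else 2
    view_embedding = embed(table, d_low=d_view, k=config.discovery.k,
                           seed=config.discovery.seed,
                           n_epochs=config.discovery.n_epochs)
    report.stage_seconds["view_embed"] = clock() - t0

    if ground_truth is not None:
        scored = metrics_mod.score_prediction(
            ground_truth.labels, assignment.labels, exclude=(UNASSIGNED,)
        )
        report.metrics = {
            "f_score": scored.f_score, "ari": scored.ari, "fmi": scored.fmi,
            "v_measure": scored.v_measure,
        }
    return assignment, view_embedding, report


def make_3d_view(embedding: Embedding, assignment: ClusterAssignment,
                 mode: str = "label_index") -> pd.DataFrame:
    """Coordinate table (cell_id, label, source, x, y, z) for 3-D display.

    ``label_index`` puts the final label's integer index on Z over a 2-D
    embedding (canonical populations first, then novel clusters, then
    noise); ``third_embedding_dim`` passes 3-D coordinates through with the
    label as a colour attribute.
    """
    coords = embedding.coords
    if coords.shape[0] != assignment.n_cells:
        raise ValueError("embedding and assignment cover different cells")
    if mode == "label_index":
        if embedding.n_dim != 2:
            raise ValueError("label_index mode requires a 2-D embedding")
        z = assignment.label_indices().astype(float)
    elif mode == "third_embedding_dim":
        if embedding.n_dim != 3:
            raise ValueError("third_embedding_dim mode requires a 3-D embedding")
        z = coords[:, 2]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame({
        "cell_id": assignment.cell_ids,
        "label": assignment.labels,
        "source": assignment.source,
        "x": coords[:, 0],
        "y": coords[:, 1],
        "z": z,
    })


class CellTypeIdentifier(BaseEstimator):
    """The full identification flow as a scikit-learn style estimator.

    ``fit(X, y)`` takes the expression matrix (already transformed) and a
    per-cell label vector in which ungated cells are the string
    ``"unassigned"``; after fitting, ``labels_`` holds the final per-cell
    assignment, ``sources_`` its provenance, ``embedding_`` the
    visualization coordinates and ``report_`` the run accounting.
    """

    def __init__(self, classifier_config=None, filter_config=None,
                 calibration_config=None, discovery_config=None,
                 viz_config=None, random_state=0):
        self.classifier_config = classifier_config
        self.filter_config = filter_config
        self.calibration_config = calibration_config
        self.discovery_config = discovery_config
        self.viz_config = viz_config
        self.random_state = random_state

    def _config(self) -> PipelineConfig:
        base = PipelineConfig.with_seed(self.random_state)
        return PipelineConfig(
            classifier=self.classifier_config or base.classifier,
            filter=self.filter_config or base.filter,
            calibration=self.calibration_config or base.calibration,
            discovery=self.discovery_config or base.discovery,
            viz=self.viz_config or base.viz,
        )

    def fit(self, X, y, ground_truth=None):
        if isinstance(X, MarkerTable):
            table = X
        else:
            X = np.asarray(X, dtype=float)
            table = MarkerTable(
                values=X,
                marker_names=[f"marker_{j}" for j in range(X.shape[1])],
                cell_ids=[f"cell_{i}" for i in range(X.shape[0])],
                transformed=True,
            )
        if isinstance(y, LabelVector):
            labels = y
        else:
            y = np.asarray(y, dtype=object)
            names = [str(v) for v in pd.unique(y[y != UNASSIGNED])]
            labels = LabelVector(y, population_names=names)
        assignment, embedding, report = run(table, labels, self._config(),
                                            ground_truth=ground_truth)
        self.assignment_ = assignment
        self.labels_ = assignment.labels
        self.sources_ = assignment.source
        self.embedding_ = embedding
        self.report_ = report
        return self

    def fit_predict(self, X, y, ground_truth=None):
        return self.fit(X, y, ground_truth=ground_truth).labels_
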