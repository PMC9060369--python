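"""Confidence filtering and Spearman-correlation feedback calibration.

After classification, cells whose best-class posterior falls below a cutoff
are moved to an "unknown" pool; the cutoff is either a fixed probability or,
by default, the 5th percentile of each population's own max-posterior
histogram (so roughly 5% of cells are rejected overall).  A feedback loop
then reconsiders each rejected cell: if its average Spearman rank
correlation with the members of some canonical population exceeds that
population's internal average correlation r_j, the cell is reallocated to
the population with which it correlates most strongly.  Passes repeat,
recomputing the thresholds, until a fixed point or an iteration cap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import rankdata

from .classify import PosteriorMatrix
from .io import NOISE, UNASSIGNED, MarkerTable

#: Label a cell carries while sitting in the unknown pool.
UNKNOWN = "unknown"

SOURCE_CLASSIFIED = "classified"
SOURCE_CALIBRATED = "calibrated"
SOURCE_NOVEL = "novel_cluster"
SOURCE_NOISE = "noise"

DEFAULT_PERCENTILE = 5.0
DEFAULT_SUBSAMPLE = 200
DEFAULT_MAX_ITERATIONS = 10


@dataclass(frozen=True)
class FilterConfig:
    """Rejection rule: fixed posterior cutoff or per-population percentile."""

    threshold_mode: str = "per_population_percentile"
    threshold_value: float = DEFAULT_PERCENTILE

    def __post_init__(self) -> None:
        if self.threshold_mode == "fixed":
            if not 0 < self.threshold_value < 1:
                raise ValueError("fixed threshold must lie in (0, 1)")
        elif self.threshold_mode == "per_population_percentile":
            if not 0 < self.threshold_value < 100:
                raise ValueError("percentile must lie in (0, 100)")
        else:
            raise ValueError(f"unknown threshold mode {self.threshold_mode!r}")


@dataclass(frozen=True)
class ClusterAssignment:
    """Per-cell final labels with their provenance.

    Labels come from canonical population names, novel cluster names, or the
    NOISE/UNKNOWN sentinels; ``source`` records which stage produced each.
    """

    labels: np.ndarray
    source: np.ndarray
    cell_ids: list[str]
    canonical_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=object)
        source = np.asarray(self.source, dtype=object)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "source", source)
        if not len(labels) == len(source) == len(self.cell_ids):
            raise ValueError("labels, source and cell_ids must align")

    @property
    def n_cells(self) -> int:
        return len(self.labels)

    def novel_names(self) -> list[str]:
        names = sorted({l for l, s in zip(self.labels, self.source)
                        if s == SOURCE_NOVEL})
        return names

    def label_indices(self) -> np.ndarray:
        """Deterministic integer index per label: canonical populations in
        training order, then novel clusters, then noise/unknown."""
        ordering = list(self.canonical_names)
        ordering += [n for n in self.novel_names() if n not in ordering]
        for sentinel in (NOISE, UNKNOWN, UNASSIGNED):
            if sentinel not in ordering:
                ordering.append(sentinel)
        index = {name: i for i, name in enumerate(ordering)}
        return np.array([index.get(l, len(ordering)) for l in self.labels])


@dataclass(frozen=True)
class CalibrationThresholds:
    """Per-population mean within-population Spearman correlation r_j."""

    r_by_population: dict
    sample_size_used: dict

    def __post_init__(self) -> None:
        for name, r in self.r_by_population.items():
            if not -1 - 1e-9 <= r <= 1 + 1e-9:
                raise ValueError(f"r_{name} = {r} outside [-1, 1]")


def filter_low_confidence(
    posteriors: PosteriorMatrix,
    config: FilterConfig | None = None,
    cell_ids: list[str] | None = None,
    reference: PosteriorMatrix | None = None,
) -> tuple[ClusterAssignment, np.ndarray]:
    """Split cells into confidently-classified and unknown by max posterior.

    Fixed mode compares every cell's max posterior to one cutoff Th.  In
    percentile mode the cutoff for population j is the stated percentile of
    the max-posterior histogram among cells whose argmax is j; when a
    ``reference`` posterior matrix is supplied (in the pipeline: the gated
    cells, whose population membership is known), its cells build the
    histograms and the cutoffs are then applied to the filtered cohort —
    this is what lets cells from populations absent at training drop below
    their claimed population's confidence profile.  Returns the assignment
    (unknown cells labeled UNKNOWN) and the unknown index set.
    """
    config = config or FilterConfig()
    if len(posteriors.population_names) == 0:
        raise ValueError("posterior matrix has no populations")
    maxp = posteriors.max_posterior
    winners = posteriors.argmax_labels
    n = len(maxp)
    if config.threshold_mode == "fixed":
        cutoffs = np.full(n, config.threshold_value)
    else:
        hist_source = reference if reference is not None else posteriors
        if reference is not None and reference.population_names != posteriors.population_names:
            raise ValueError("reference and posteriors must share population names")
        ref_maxp = hist_source.max_posterior
        ref_winners = hist_source.argmax_labels
        cutoffs = np.zeros(n)
        for name in posteriors.population_names:
            members = winners == name
            if not members.any():
                continue
            ref_members = ref_winners == name
            pool = ref_maxp[ref_members] if ref_members.any() else maxp[members]
            cutoffs[members] = np.percentile(pool, config.threshold_value)
    keep = maxp >= cutoffs
    labels = np.where(keep, winners, UNKNOWN).astype(object)
    source = np.where(keep, SOURCE_CLASSIFIED, UNKNOWN).astype(object)
    if cell_ids is None:
        cell_ids = [f"cell_{i}" for i in range(n)]
    assignment = ClusterAssignment(labels, source, list(cell_ids),
                                   canonical_names=list(posteriors.population_names))
    return assignment, np.flatnonzero(~keep)


def _rank_zscores(values: np.ndarray) -> np.ndarray:
    """Per-cell standardised marker ranks; Spearman corr = z_a . z_b / n."""
    ranks = np.apply_along_axis(rankdata, 1, values)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1, keepdims=True))
    # constant marker vector -> zero vector -> correlation 0 with everything
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(norms > 0, centered / norms, 0.0)
    return z


def _population_members(assignment: ClusterAssignment) -> dict:
    members: dict[str, np.ndarray] = {}
    for name in assignment.canonical_names:
        idx = np.flatnonzero(assignment.labels == name)
        if len(idx):
            members[name] = idx
    return members


def compute_thresholds(
    table: MarkerTable,
    assignment: ClusterAssignment,
    max_cells_per_population: int = DEFAULT_SUBSAMPLE,
    seed: int = 0,
) -> CalibrationThresholds:
    """r_j = mean pairwise Spearman correlation within population j.

    Populations are subsampled to ``max_cells_per_population`` cells (seeded)
    before the O(m^2) pair average; populations with fewer than 2 assigned
    cells are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    r_by_pop: dict[str, float] = {}
    sizes: dict[str, int] = {}
    for name, idx in _population_members(assignment).items():
        if len(idx) < 2:
            warnings.warn(f"population {name!r} has < 2 cells; r_j undefined, skipped")
            continue
        if len(idx) > max_cells_per_population:
            idx = rng.choice(idx, size=max_cells_per_population, replace=False)
        z = _rank_zscores(table.values[idx])
        corr = z @ z.T
        m = len(idx)
        r_by_pop[name] = float((corr.sum() - np.trace(corr)) / (m * (m - 1)))
        sizes[name] = m
    if len(r_by_pop) < 2:
        raise ValueError("fewer than 2 populations with a defined threshold")
    return CalibrationThresholds(r_by_population=r_by_pop, sample_size_used=sizes)


def calibrate(
    table: MarkerTable,
    assignment: ClusterAssignment,
    unknown_indices: np.ndarray,
    thresholds: CalibrationThresholds | None = None,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
    max_cells_per_population: int = DEFAULT_SUBSAMPLE,
    seed: int = 0,
) -> tuple[ClusterAssignment, np.ndarray, list]:
    """Iteratively reallocate unknown cells whose correlation beats r_j.

    Each pass: every unknown cell's average Spearman correlation with a
    seeded subsample of each canonical population is computed; cells
    exceeding at least one population's r_j move to the population of
    highest correlation with source ``calibrated``.  Thresholds are
    recomputed between passes.  Stops at a fixed point or after
    ``max_iterations`` passes.  Returns (assignment, remaining unknown
    indices, per-pass reallocation log).
    """
    labels = assignment.labels.copy()
    source = assignment.source.copy()
    unknown = np.array(sorted(unknown_indices), dtype=int)
    log: list[dict] = []
    rng = np.random.default_rng(seed)
    for iteration in range(max_iterations):
        if len(unknown) == 0:
            break
        current = replace(assignment, labels=labels, source=source)
        thr = (thresholds if iteration == 0 and thresholds is not None
               else compute_thresholds(table, current,
                                       max_cells_per_population,
                                       seed=int(rng.integers(2**31 - 1))))
        pops = sorted(thr.r_by_population)
        z_unknown = _rank_zscores(table.values[unknown])
        mean_corr = np.empty((len(unknown), len(pops)))
        for j, name in enumerate(pops):
            idx = np.flatnonzero(labels == name)
            if len(idx) > max_cells_per_population:
                idx = rng.choice(idx, size=max_cells_per_population, replace=False)
            z_pop = _rank_zscores(table.values[idx])
            mean_corr[:, j] = (z_unknown @ z_pop.T).mean(axis=1)
        r_vec = np.array([thr.r_by_population[p] for p in pops])
        exceeds = mean_corr > r_vec
        movers = exceeds.any(axis=1)
        if not movers.any():
            break
        # among populations whose threshold is beaten, take the highest corr
        masked = np.where(exceeds, mean_corr, -np.inf)
        best = np.argmax(masked, axis=1)
        moved = {}
        for cell, j in zip(unknown[movers], best[movers]):
            labels[cell] = pops[j]
            source[cell] = SOURCE_CALIBRATED
            moved[pops[j]] = moved.get(pops[j], 0) + 1
        unknown = unknown[~movers]
        log.append({"iteration": iteration, "reallocated": int(movers.sum()),
                    "by_population": moved})
    final = replace(assignment, labels=labels, source=source)
    return final, unknown, log
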