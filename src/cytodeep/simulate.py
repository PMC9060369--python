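"""Synthetic CyTOF-like cohorts with planted canonical and novel populations.

The generative model is a Gaussian mixture on the arcsinh-transformed scale:
each population is a multivariate normal in marker space, populations are
well separated relative to their within-population spread, a configurable
fraction of cells from "labeled" populations carries a gated label, and
"novel" populations never appear in the labeled subset.  This mirrors the
structure of gated benchmark cohorts (tens of markers, dozens of gated
populations, roughly half of the cells unlabeled, with rare populations
present) without modelling doublets, batch effects or acquisition drift.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import UNASSIGNED, LabelVector, MarkerTable

#: Default proportion given to the planted rare canonical population.
RARE_PROPORTION = 0.015


@dataclass(frozen=True)
class PopulationSpec:
    """One mixture component: name, location, spread, abundance, gated or not."""

    name: str
    mean: np.ndarray
    covariance: np.ndarray  # diagonal vector or full PSD matrix
    proportion: float
    labeled: bool = True

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)
        if not 0 < self.proportion <= 1:
            raise ValueError(f"proportion must be in (0,1], got {self.proportion}")
        if cov.ndim == 1:
            if cov.shape[0] != mean.shape[0]:
                raise ValueError("diagonal covariance length != mean length")
            if (cov < 0).any():
                raise ValueError("negative variance")
        elif cov.ndim == 2:
            if cov.shape != (mean.shape[0], mean.shape[0]):
                raise ValueError("covariance shape incompatible with mean")
            if not np.allclose(cov, cov.T):
                raise ValueError("covariance must be symmetric")
            if np.linalg.eigvalsh(cov).min() < -1e-10:
                raise ValueError("covariance must be PSD")
        else:
            raise ValueError("covariance must be a vector or matrix")

    @property
    def full_covariance(self) -> np.ndarray:
        cov = self.covariance
        return np.diag(cov) if cov.ndim == 1 else cov


def generate(
    specs: list[PopulationSpec],
    n_cells: int,
    labeled_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[MarkerTable, LabelVector, LabelVector]:
    """Draw a cohort and return (table, observed labels, ground-truth labels).

    Cells of unlabeled specs, plus a random ``1 - labeled_fraction`` share of
    each labeled spec's cells, are UNASSIGNED in the observed labels.  The
    returned table is already on the transformed scale.  Deterministic under
    a fixed seed.
    """
    if not specs:
        raise ValueError("need at least one population spec")
    proportions = np.array([s.proportion for s in specs])
    if abs(proportions.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {proportions.sum():.6f}, expected 1")
    labeled_specs = [s for s in specs if s.labeled]
    if not labeled_specs:
        raise ValueError("at least one spec must be labeled")
    if not 0 < labeled_fraction <= 1:
        raise ValueError("labeled_fraction must be in (0, 1]")
    if n_cells < len(specs):
        raise ValueError("n_cells must be at least the number of populations")

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_cells, proportions)
    blocks, truth = [], []
    for spec, count in zip(specs, counts):
        blocks.append(
            rng.multivariate_normal(spec.mean, spec.full_covariance, size=count,
                                    method="cholesky")
        )
        truth.extend([spec.name] * count)
    values = np.vstack(blocks)
    truth = np.array(truth, dtype=object)

    perm = rng.permutation(n_cells)
    values, truth = values[perm], truth[perm]

    labeled_names = {s.name for s in labeled_specs}
    observed = truth.copy()
    observed[~np.isin(truth.astype(str), list(labeled_names))] = UNASSIGNED
    if labeled_fraction < 1:
        candidates = np.flatnonzero(observed != UNASSIGNED)
        n_hide = int(round((1 - labeled_fraction) * len(candidates)))
        hide = rng.choice(candidates, size=n_hide, replace=False)
        observed[hide] = UNASSIGNED

    table = MarkerTable(
        values=values,
        marker_names=[f"marker_{j}" for j in range(values.shape[1])],
        cell_ids=[f"cell_{i}" for i in range(n_cells)],
        transformed=True,
    )
    pop_names = [s.name for s in specs]
    observed_lv = LabelVector(observed, population_names=[s.name for s in labeled_specs])
    truth_lv = LabelVector(truth, population_names=pop_names)
    return table, observed_lv, truth_lv


def default_benchmark_spec(
    k_canonical: int,
    m_novel: int,
    n_markers: int,
    separation: float = 6.0,
    seed: int = 0,
    sigma: float = 1.0,
    include_rare: bool = True,
) -> list[PopulationSpec]:
    """Place k labeled + m novel spherical Gaussians with a minimum separation.

    Population means are sampled uniformly over the dynamic range of
    arcsinh-transformed cytometry intensities (about 8 within-population
    standard deviations per marker) by greedy rejection, enforcing a minimum
    pairwise distance of ``separation * sigma``; packings that do not fit in
    that range are an error.  One canonical population is made rare (<2%)
    by default, reflecting the rare-subset discovery setting.
    """
    if k_canonical < 2:
        raise ValueError("k_canonical must be >= 2")
    if m_novel < 0:
        raise ValueError("m_novel must be >= 0")
    if n_markers < 2:
        raise ValueError("n_markers must be >= 2")
    n_pop = k_canonical + m_novel
    rng = np.random.default_rng(seed)
    min_dist = separation * sigma
    box = 8.0 * sigma  # arcsinh-transformed intensities span roughly [0, 8]
    means: list[np.ndarray] = []
    attempts = 0
    while len(means) < n_pop:
        candidate = rng.uniform(0, box, size=n_markers)
        if all(np.linalg.norm(candidate - m) >= min_dist for m in means):
            means.append(candidate)
        attempts += 1
        if attempts > 2000 * n_pop:
            raise ValueError(
                f"infeasible packing: cannot place {n_pop} populations at "
                f"separation {separation} in {n_markers} dimensions"
            )

    proportions = np.full(n_pop, 1.0 / n_pop)
    if include_rare and n_pop >= 3:
        proportions = np.full(n_pop, (1.0 - RARE_PROPORTION) / (n_pop - 1))
        proportions[k_canonical - 1] = RARE_PROPORTION
    specs = []
    for i in range(n_pop):
        novel = i >= k_canonical
        specs.append(
            PopulationSpec(
                name=f"novel_{i - k_canonical + 1}" if novel else f"pop_{i + 1}",
                mean=means[i],
                covariance=np.full(n_markers, sigma**2),
                proportion=float(proportions[i]),
                labeled=not novel,
            )
        )
    return specs


def save_specs(specs: list[PopulationSpec], path: str | Path) -> None:
    """Serialise population specs to JSON (diagonal covariances only)."""
    records = []
    for s in specs:
        cov = s.covariance if s.covariance.ndim == 1 else np.diag(s.full_covariance)
        records.append(
            {"name": s.name, "mean": s.mean.tolist(), "covariance": cov.tolist(),
             "proportion": s.proportion, "labeled": s.labeled}
        )
    Path(path).write_text(json.dumps(records, indent=1))


def load_specs(path: str | Path) -> list[PopulationSpec]:
    records = json.loads(Path(path).read_text())
    return [
        PopulationSpec(
            name=r["name"], mean=np.array(r["mean"]),
            covariance=np.array(r["covariance"]),
            proportion=r["proportion"], labeled=r["labeled"],
        )
        for r in records
    ]
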