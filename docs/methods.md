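# Methods

## The identification model

`cytodeep` treats cell-type identification in a partially gated CyTOF
cohort as three coupled problems: supervised recognition of the gated
("canonical") populations, rejection of cells that belong to none of them,
and unsupervised discovery of structure among the rejected cells.

**Classifier.** A fully connected network maps the arcsinh-transformed
marker vector `x ∈ R^n` to a posterior over the K canonical populations
through hidden layers (default widths 128/64/32) with ReLU activations
(softplus selectable) and a softmax output. The training objective is the
mean cross-entropy of the one-hot labels plus an L2 penalty `λ Σ w²` over
the weight matrices (biases unpenalised; default `λ = 1e-4`), minimised by
mini-batch Adam (learning rate 0.001, batch 256, β₁=0.9, β₂=0.999). The
net is implemented in NumPy with hand-derived backpropagation; the test
suite checks the analytic gradient against central finite differences on a
small network, including the dropout path with a frozen mask. Training
holds out a stratified 10% validation split and stops early when the
validation cross-entropy has not improved for a patience window, restoring
the best parameters.

Two optimisation defaults are *step-budgeted* rather than fixed, because
the same learning rate and batch size must serve cohorts from a few hundred
to hundreds of thousands of gated cells. With `epochs=None` the epoch
budget is `ceil(2000 / batches_per_epoch)`, clamped to [100, 1000], so a
small cohort still receives roughly 2,000 Adam steps; the early-stopping
patience is likewise raised to cover at least ~500 stalled steps. Without
this, a cohort with two batches per epoch trains for tens of steps, and the
resulting underfit posteriors corrupt everything downstream (the filter's
reference histograms flatten and rare populations are abandoned before they
are learned). Explicit `epochs`/`patience` values are always honoured.

No class weighting is applied; splits are stratified. Class imbalance is
handled only through the rare population's own labeled cells, which is why
a minimum of 5 labeled cells per population is enforced.

**Hyperparameter search.** `tune_hyperparameters` runs a canonical
global-best particle swarm over (number of hidden layers, log₁₀ λ, dropout
rate) with the standard constriction coefficients (inertia 0.72, cognitive
= social = 1.49), positions clipped to the box and the integer dimension
rounded. The objective is the macro-average one-vs-rest ROC area on a
stratified half/half train/validation split of the gated cells; ties break
toward the first-evaluated configuration.

**Confidence filter.** For each scored cell the confidence is the maximum
posterior. In `fixed` mode a single cutoff Th is applied. In the default
`per_population_percentile` mode the cutoff for population j is the 5th
percentile of the max-posterior histogram of cells claimed by j, and the
histogram is built from a *reference* cohort — in the pipeline, the gated
cells, the one set of cells whose membership in each population is known.
This choice is load-bearing: the gated cells of a well-separated population
are classified with near-unit confidence, so the 5th-percentile cutoff sits
extremely high, and a cell from a population that was absent at training
almost always scores below it even when the softmax itself is fairly
confident. Building the histogram from the cohort being filtered instead
caps rejection at the percentile (≈5%) per population by construction and
lets confidently misassigned novel cells through; that mode remains the
fallback when no reference is supplied. Under either mode, a cohort drawn
from the canonical populations alone loses ≈5% of its cells to the unknown
pool, matching the design intent of the 5% threshold.

**Feedback calibration.** For population j, the threshold `r_j` is the
mean pairwise Spearman rank correlation (average ranks on ties) across
markers between that population's assigned cells, estimated on a seeded
subsample (default 200 cells per population, an O(q·N) → O(q·200) cost
control). Each unknown cell's average correlation with each population's
subsample is compared against `r_j`; cells exceeding at least one threshold
move to the population of highest correlation, with provenance
`calibrated`. Passes repeat — thresholds recomputed from the updated
assignment each time — until no cell moves or 10 passes have run.
Reallocation is strictly one-way (unknown → canonical); cells are never
moved between canonical populations and never removed from one. Because
admission requires a correlation above the population *mean*, at most
roughly half of a population's own rejected tail can ever be reclaimed in
one pass; the loop therefore reduces, but does not eliminate, stranded
canonical cells. Since Spearman correlation is invariant to monotone
per-marker transforms, the raw/transformed choice is immaterial here.

**Discovery.** The residual unknown cells are embedded with UMAP
(`n_neighbors = k`, default 20; 2-D by default) and clustered in the
embedding with HDBSCAN. The fuzzy k-NN graph the embedding optimises
against is also implemented directly: per-point nearest-neighbor distance
ρ_i, bandwidth σ_i calibrated by binary search so the neighbor weight mass
equals log₂(k) (smooth-kNN calibration), directed weights
`exp(−(d−ρ_i)/σ_i)` and fuzzy-union symmetrisation `w + wᵀ − w∘wᵀ`; the
achieved edge-wise cross-entropy between the graph and the embedding's
low-dimensional kernel is reported on the Embedding object as a
diagnostic. Mutual reachability and its max rule are implemented from the
definition and verified on hand values; the embedding optimiser and
condensed-tree extraction are delegated to umap-learn and scikit-learn.
scikit-learn's HDBSCAN does not expose per-cluster condensed-tree
stabilities, so the clustering summary carries per-cluster sizes and mean
membership probability instead.

Two extraction details matter in this pipeline:

- *Minimum cluster size.* Default `max(15, 2% of the pool)`. The unknown
  pool is never pure: the confidence filter rejects the bottom ≈5% of every
  canonical population and calibration reclaims only part of that tail, so
  the pool contains one tight clump of leftovers per canonical population,
  each typically around 1% of the pool. A minimum cluster size above that
  contamination scale keeps those clumps out of the reported novel
  populations (they fall to noise), while any novel population of practical
  interest is far larger.
- *Density cut and root selection.* The pipeline extracts clusters with
  `allow_single_cluster=True` and a cluster-selection epsilon set
  automatically to the 95th percentile of the embedding's k-NN distances.
  Pure excess-of-mass selection can never select the hierarchy's root, so a
  pool dominated by a single novel population would dissolve into noise
  plus density-fluctuation micro-clusters; merging hierarchy levels below
  the typical within-population neighbor distance and allowing root
  selection recovers it as one cluster, while genuinely distinct
  populations — separated in the embedding by gaps far larger than that
  scale — remain separate. The low-level `cluster_unknown` keeps the
  conservative defaults (no root selection, no cut), under which a
  structureless pool correctly comes back as noise.

Discovered clusters are named `new_1, new_2, …` by decreasing size,
skipping names already in use; noise cells keep the `noise` label and are
reported as unassigned rather than forced into a cluster.

**3-D view.** The default export places a 2-D embedding on X/Y and the
final label's integer index on Z (canonical populations in training order,
then novel clusters, then noise), which separates populations into parallel
planes; alternatively a 3-D embedding is passed through with the label as a
colour attribute. Both modes are exact descriptions of the output table,
and neither is canonical.

## Evaluation measures

All external indices are computed from an explicit true-by-predicted
contingency table `N_ij`:

- **Weighted F-score** `F = Σ_i (C_i/N) F_i` with
  `F_i = 2·P_i·R_i/(P_i+R_i)`. The harmonic-mean factor 2 is used — without
  it, perfect agreement would score 0.5 rather than the anchor value 1.0.
  Predicted clusters are matched to classes by maximum overlap
  (majority vote, many-to-one), so unsupervised clusterings can be scored;
  for a classifier whose labels already coincide with the classes the
  mapping is the identity.
- **ARI** from pair counts `Σ C(N_ij,2)` with the standard
  expected/maximum-index normalisation; in the degenerate case (expected =
  maximum) it is 1 for identical partitions and 0 otherwise.
- **FMI** `sqrt(TP/(TP+FP) · TP/(TP+FN))` over cell pairs; 0 when TP = 0.
- **V-measure**: homogeneity `1 − H(C|K)/H(C)` and completeness
  `1 − H(K|C)/H(K)` from the contingency entropies (1 when the normalising
  entropy is 0), combined by harmonic mean.
- **NPE**: for each cell the fraction of its k nearest neighbors sharing
  its subtype is computed in the original space and in the embedding; per
  subtype, the two empirical distributions of that fraction over the
  support {0, 1/k, …, 1} are compared by total-variation distance
  `½ Σ |P_s − Q_s|`, and the per-cell average of the subtype distances is
  returned. This is the reading under which an identity embedding gives
  exactly 0. Subtypes with fewer than 2 cells are skipped with a warning.
- **Residual variance** `1 − R²` between matched distance vectors; defined
  as 1 when either vector is constant (no correlation is possible).
- **ROC area** by the rank statistic (ties count ½), which equals the
  trapezoidal area under TPR-vs-FPR; 4-fold stratified cross-validation
  reports per-population one-vs-rest areas, excluding (with a warning) any
  population absent from a fold.

The tests verify ARI, FMI, V-measure and the weighted F against exhaustive
pair-enumeration/entropy oracles on *every* pair of set partitions of up to
6 elements, and against scikit-learn on random partitions.

## Synthetic cohorts

The generator draws each population from a multivariate Gaussian on the
arcsinh-transformed scale — the minimal structure under which the
classifier's and clustering's assumptions hold — with population means
placed by greedy rejection in the transformed dynamic range (≈[0, 8] per
marker at unit within-population σ) subject to a minimum pairwise
separation (default 6σ, the "well-separated" regime); an infeasible
packing raises an error. Counts follow a multinomial over the declared
proportions; one canonical population is rare (1.5%) by default, since
rare-subset discovery is a core use case. Populations flagged novel never
appear among the observed labels, and a configurable fraction (default
50%, matching the roughly half-gated benchmark cohorts this emulates) of
each labeled population's cells is also hidden. Output is byte-identical
under a fixed seed.

What the generator does *not* emulate: heavy-tailed measurement noise,
zero inflation, doublets, batch effects, acquisition drift, or correlated
(non-diagonal) marker covariance unless explicitly specified. Passing
tests on these cohorts therefore demonstrates the pipeline's mechanics —
rejection calibrated to the gated confidence profile, one-way correlation
feedback, density-cluster recovery of planted structure — not robustness
to real-data artefacts. Batch-effect correction is the user's
responsibility upstream of this package.

## Numerical and degenerate-input conventions

- Softmax is computed with max-subtraction; softplus as `log1p(exp(·))`
  via `logaddexp`; cross-entropies clip probabilities at 1e-12 (1e-9 for
  graph weights, which are also clipped below 1 so the complement term is
  finite; coordinates are promoted to float64 first, since float32 rounds
  `1 − 1e-9` to 1).
- A cell whose marker ranks are all tied has an undefined rank correlation;
  it is given correlation 0 with everything.
- σ_i calibration uses 64 bisection steps with tolerance 1e-5 on the
  weight mass and floors σ at 1e-12.
- Determinism: every source of randomness is an explicit seed; UMAP is run
  with a fixed `random_state`, which also forces single-threaded layout.
  Training is deterministic given seed and thread count.
- Fixed-mode filtering requires Th ∈ (0,1); percentile mode (0,100).
  Filtering keeps cells at exactly the cutoff (`≥`).
- PSO with a single-point search space evaluates it and returns it; the
  first-evaluated configuration wins ties.

## Known limitations

- Rejection of unseen populations relies on the softmax confidence
  profile. A novel population lying deep inside one canonical population's
  confidence region (as happens occasionally in low dimension with few
  classes) is misclassified with high confidence and cannot be recovered
  downstream; canonical-call precision degrades gracefully (a few percent)
  rather than catastrophically in the regimes tested.
- The mean-correlation admission rule bounds calibration recall: stranded
  canonical cells are roughly halved, not eliminated, so a few percent of
  each population's tail ends as noise in the unknown pool. This is
  inherent to the rule, not a tuning artefact.
- `r_j` is estimated on subsamples; the monotone before/after comparison
  of within-population correlation holds up to that sampling noise (the
  tests allow 0.01).
- FCS support is read-only, covers the common float/double/uniform-32-bit
  integer layouts of FCS 3.0/3.1, and ignores compensation keywords.
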