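# Methods

This note documents the models implemented in `tempoclust`, the
defaults and why they were chosen, what the synthetic cohort generator
does and does not emulate, and the numerical choices that matter when
reproducing results.

## Trajectory representation

A learner is the vector of completion days of the tasks they finished,
ordered by curriculum position. Never-completed tasks are **dropped**
from the vector, yielding unequal lengths that DTW handles natively;
an alternative would be to impute skipped tasks at a sentinel time
(course end plus a penalty), which changes the geometry — dropping is
the default because skipping is then penalised only through the length
and shape mismatch it actually produces, not through an arbitrary
penalty constant. Learners with zero completions carry no temporal
information and are excluded before the similarity stage.

## DTW kernel

`dtw_distance` is the classic dynamic program on the n×m grid with
local cost `(x_i − y_j)²`, step set {right, down, diagonal}, full
boundary alignment (1,1)→(n,m), no warping window and no slope
weighting. The cumulative cost is accumulated in double precision; the
inner loop is numba-compiled with a pure-Python fallback.

The kernel is `k = exp(−D/σ²)`. σ is a free parameter: the default is
the median heuristic, σ² = median off-diagonal DTW distance of the
cohort, which is scale-free (invariant to the choice of time unit) and
maps the median pair to similarity e⁻¹. A fixed σ can be supplied
instead (`sigma_rule="fixed"`), which is required when similarity
matrices from different cohorts must be comparable.

Constrained DTW (Sakoe–Chiba bands), end-point-invariant DTW and
lower-bounding accelerations are deliberately out of scope.

## RMST graph construction

Sparsification operates on DTW **distances**; the surviving edges are
weighted by the kernel **similarities**. The keep rule is

    d_ij < mlink_ij + γ (d_i^(k) + d_j^(k)),

with `mlink_ij` the bottleneck (largest) edge on the MST path between
i and j and `d_i^(k)` the k-th nearest-neighbour distance, a local
noise scale. Defaults γ = 0.5, k = 1. γ = 0 keeps little beyond the
MST; γ → ∞ recovers the complete graph; the mask is provably monotone
in γ and always contains the MST, so the graph is always connected.
MST ties are broken lexicographically on (distance, min id, max id)
for determinism. The selected partitions are empirically stable for
γ across [0.25, 1] (asserted as a VI ≤ 0.3 test on planted cohorts).

## Markov Stability

The partition quality at Markov time t is the trace of

    R(t; H) = Hᵀ (Π e^{−tL} − πᵀπ) H,

with L = D − A the combinatorial Laplacian and π the stationary
measure of the diffusion. For `p(t) = p(0) e^{−tL}` the left null
vector of L is uniform, so π = 1/N **uniform** is the default;
a degree-proportional π (matching the discrete-time chain Q = D⁻¹A)
is available via `pi_mode="degree"` and recorded in all scan metadata.
The Markov Stability is `r(t, H) = min_{τ≤t} Tr R(τ; H)`, evaluated
over grid points; at the first grid point, where no τ < t exists, τ = t
is used.

Numerical notes:

- `e^{−tL}` is computed from one symmetric eigendecomposition of L
  (eigenvalues clipped at 0), reused across the whole grid; row sums
  are conserved to 1e−10 at all grid times.
- For uniform π the trace `Tr R(τ; H)` is non-increasing in τ for
  fixed H (its spectral coefficients `(v_kᵀ h_c)²/N` are nonnegative
  and decay as `e^{−τλ_k}`), so the min over τ ≤ t equals the trace at
  t; the scan exploits this when ranking restart candidates and falls
  back to the explicit grid minimum for degree-weighted π. The
  reported r*(t) is always the literal grid minimum, so it agrees
  exactly with a recomputation through `stability()`.

Optimisation is a Louvain-style greedy on the dense generalized
modularity matrix `B(t) = Π e^{−tL} − πᵀπ`: node-moving sweeps in a
seed-shuffled order with per-node best-candidate moves (gain threshold
1e−12, ties to the lower community id, 100-pass cap per level),
followed by community aggregation `B ← HᵀBH`, repeated until no move
improves. Each Markov time runs ℓ = 100 restarts by default with
seeds spawned hierarchically from one master seed, so results are
reproducible and independent of execution order.

### Scale selection

Two robustness signals are computed: VI(t), the mean pairwise
normalised variation of information across the restart ensemble
(consistency of the optimisation), and VI(t, t′) between best
partitions at different times (persistence across scales). VI is
normalised by log N to [0, 1]. Candidates are contiguous grid runs
where the community count is constant and the off-diagonal mean of the
VI(t, t′) block is below θ_plateau = 0.1, of length ≥ L_min = 5 grid
points; within a block the partition at the t minimising the
(window-3 smoothed) VI(t) is returned. Candidates are ranked by
plateau length, then VI dip depth. Both thresholds are configurable
and the raw curves are exposed, since "robust" is ultimately an
analyst's judgement. An empty candidate list is a meaningful outcome:
it signals a lack of natural clusters. The quasi-hierarchy across
scales is *reported* (a containment score between consecutive
candidates), never asserted — it is an empirical property of data, not
a guarantee of the method.

The default grid is 100 log-spaced points in [10⁻², 10²]. At t ≪ 1
the propagator is near the identity and the singleton partition is
optimal by construction, so grids for graphs known to have order-1
structure (e.g. the two-clique toys in the tests) sensibly start at
t = 1.

## Characterisation

- **Massed sessions.** Completion times ordered by task index are made
  monotone by exact least-squares isotonic regression (PAVA, via
  scikit-learn); maximal runs of fitted times differing by ≤ tol_days
  (default 0) are sessions, and the statistic is the mean session size
  in tasks, singletons included. Including singletons anchors the
  statistic at 1 for perfectly spread-out learners; excluding them is
  a plausible alternative convention, so the tolerance and the block
  structure are both exposed.
- **Completion fraction** is completions over curriculum size.
- **GP trajectories.** Cluster members' cumulative completion counts
  versus day are pooled and fitted with a constant × RBF +
  white-noise kernel, hyperparameters by marginal-likelihood
  maximisation (5 optimiser restarts by default), `normalize_y`
  enabled. GP cost is cubic in the design size, so pooling thins each
  member's curve evenly to keep at most ~400 total points; this bounds
  a fit at well under a second without visibly changing the mean
  curve at cohort scales.
- **Bayes factor.** `log K = Σ_c log ML(cluster c) − log ML(pooled)`
  with equal model priors. The default refits hyperparameters per
  cluster (each cluster model is its best self); a fixed-hyperparameter
  variant (`refit_hyperparameters=False`) scores clusters under the
  pooled model's kernel, isolating the data split from hyperparameter
  flexibility. A single-cluster "partition" compares a model with
  itself and returns log K = 0 exactly. Note that for a homogeneous
  cohort split at random, log K is typically slightly *negative*
  (splitting halves the evidence each model sees) — small |log K| is
  the expected null behaviour, large positive log K the signal.
- **Enrichment.** Upper-tail hypergeometric probability
  P(X ≥ hits) per cluster; with several clusters tested, raw and
  Bonferroni-adjusted p-values are both reported. Grade banding uses
  low < 60 and high > 70 (on a 0–100 scale) by default.
- **Classifier baseline.** RBF-SVM and depth-4 decision tree on
  z-scored (massed-session length, completion fraction) features,
  reporting per-class training-set counts — a deliberately simple
  feature-based comparison surface, not a tuned predictive model.

## Synthetic cohorts

The generator emulates a fixed curriculum (default 376 tasks split
evenly over three 70-day terms, due dates evenly spaced within terms)
and five archetypes:

| archetype   | offset (d) | offset sd | jitter sd | skip | other |
|-------------|-----------:|----------:|----------:|-----:|-------|
| early_bird  | −10 | 2 | 1   | 0.05 | |
| on_time     |   0 | 2 | 1   | 0.05 | |
| low_engager |  +2 | 2 | 1.5 | 0.05 | drift +12 d by course end; extra skip 0.3 after day 140 |
| crammer     |   0 | 2 | 1   | 0.30 | 2 single-day sessions/term, ≤ 2 d before the block deadline |
| sporadic    |  +5 | 5 | 10  | 0.15 | adjacent-swap shuffling with p = 0.5 |

Each learner's systematic offset is drawn once per learner
(`N(offset, offset_sd)`); individual completions jitter around the
shifted due date with sd `jitter_sd`. This hierarchical structure is
what makes an offset "systematic": the alternative — i.i.d. per-task
noise at the group level — plants no recoverable group structure,
because DTW warps away constant offsets between monotone ramps while
i.i.d. jitter dominates the distances. Low engagers accrue additional
lateness linearly over the course (waning engagement); crammers
complete each term's tasks in contiguous blocks on single session days
anchored just before the block's deadline; sporadic learners swap
adjacent completions (a `global` shuffle mode permuting a random
subset is also provided, since persistent out-of-order behaviour could
be modelled either way). Skipped tasks are absent rows, not sentinels.
One master seed spawns one RNG substream per learner, so extending a
cohort never perturbs existing learners and identical inputs give
byte-identical tables.

Grades, when needed for enrichment tests, are sampled from an
archetype → Normal(mean, sd) map (crammers lowest on average); they
are a labelling device, not a mechanistic model of performance.

What the generator does **not** emulate: real cohorts' heavy-tailed
session-length distributions, within-learner behavioural change across
terms (e.g. a learner who crams only in term 3), holidays and deadline
extensions, and any dependence of skipping on task difficulty. Tests
passing on synthetic cohorts therefore demonstrate that the pipeline
recovers structure *of the kind planted*, not that real cohorts
contain such structure.

## Problem sizes used in the test and acceptance runs

The planted-recovery runs use 4 archetypes × 20 learners on the
376-task curriculum with the full default scan (100 Markov times ×
100 restarts), matching the scale of a one-year single-cohort study.
Louvain-versus-exhaustive checks run at N = 8 (4140 partitions);
DTW, isotonic and hypergeometric oracles enumerate exhaustively at
their tractable sizes (series length ≤ 5, vectors ≤ 5, populations
≤ 12). Bayes-factor sign tests use two clusters of six 12-point
trajectories with an offset 20× the noise sd, sizes at which the GP
evidence is computed exactly in well under a second per run.

## Known limitations

- Dense propagator and Louvain on dense B(t): memory and time are
  O(N²)–O(N³), comfortable to a few hundred learners; the linearised
  large-N approximation of e^{−tL} is not implemented.
- The DTW stage is O(n·m) per pair without lower-bounding, quadratic
  in cohort size; fine for N ≲ 500 at curriculum lengths ≲ 10³.
- The scale-selection thresholds (θ_plateau, L_min, smoothing window)
  are heuristics; pathological VI landscapes (e.g. slow drifts with no
  plateaus) yield no candidates by design.
- GP marginal likelihoods depend on the kernel family and bounds;
  Bayes factors should be read as orders of magnitude, not precise
  evidence ratios.
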