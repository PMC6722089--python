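# tempoclust

Unsupervised multiscale clustering of temporal engagement trajectories.

`tempoclust` finds groups of online learners with similar temporal
behaviour directly from raw task-completion time-series, without
pre-selecting statistical features or fixing the number of clusters in
advance. It was built for learning-analytics cohorts (hundreds of
learners completing a fixed curriculum over an academic year), but the
graph-clustering core applies unchanged to any collection of
event-time trajectories, e.g. sampling times in longitudinal studies
or activity traces in behavioural experiments.

## Method

Each learner *l* is represented by the vector of completion times
(days since course start) of the tasks they finished, ordered by
curriculum position. The pipeline has four stages:

1. **DTW kernel similarity.** Pairwise dynamic-time-warping distances
   `D(x, y)` (squared-difference local cost, unconstrained monotone
   warping) are mapped to similarities

   `k(x, y) = exp(−D(x, y) / σ²)`,

   giving an N×N similarity matrix `A` with entries in (0, 1]. By
   default σ² is the median off-diagonal DTW distance.

2. **RMST sparsification.** The complete weighted graph implied by `A`
   is pruned with the relaxed minimum spanning tree rule: edge
   (i, j) is kept iff `d_ij < mlink_ij + γ (d_i^(k) + d_j^(k))`,
   where `mlink_ij` is the largest edge on the MST path between i and
   j and `d_i^(k)` the distance to the k-th nearest neighbour. The MST
   itself is always kept, so the graph stays connected.

3. **Markov Stability clustering.** A continuous-time random walk
   `p(t) = p(0) e^{−tL}` (combinatorial Laplacian `L = D − A`) probes
   the graph at every scale. A partition with membership matrix `H` is
   scored by the trace of the block autocovariance
   `R(t; H) = Hᵀ(Π e^{−tL} − πᵀπ)H`, and its Markov Stability is
   `r(t, H) = min_{τ≤t} Tr R(τ; H)`, maximised at each Markov time t by
   a seeded, restarted Louvain-style greedy optimiser (ℓ = 100
   restarts by default). Robust scales are selected with the
   normalised variation of information: dips of VI(t) (consistency
   across restarts) inside low-VI(t, t′) plateaux (persistence across
   scales).

4. **Characterisation.** Each cluster is profiled by its mean massed
   session length (run lengths of the isotonic fit of completion time
   versus task order), task-completion fraction, and a Gaussian-process
   mean trajectory of cumulative completions; clusters are compared by
   the Bayes factor `log K = Σ_c log ML(cluster c) − log ML(pooled)`
   and tested for over-representation of low performers with an
   upper-tail hypergeometric test. An RBF-SVM / depth-4 decision-tree
   baseline on z-scored features is included for comparison.

Because real learner records are personal data, the package ships a
synthetic cohort generator that plants five behavioural archetypes
(early birds, on-time learners, low engagers, crammers, sporadic
learners) with ground-truth labels, so every stage is testable end to
end. See `docs/methods.md` for model details and limitations.

## Worked example

```python
import numpy as np
import tempoclust as tc

cur = tc.make_curriculum(376, 3, 70.0)             # 376 tasks, three 70-day terms
specs = [(tc.ARCHETYPES[a], 20) for a in
         ["early_bird", "on_time", "low_engager", "crammer"]]
cohort = tc.simulate_cohort(cur, specs, seed=0)
series = [s for s in cohort.to_event_series(376) if len(s)]

model = tc.TemporalEngagementClusterer(random_state=0).fit(series)
for c in model.report_.candidates:
    print(f"c={c.n_communities:2d}  plateau={c.plateau_length:3d} grid pts"
          f"  t=[{c.t_window[0]:.3g}, {c.t_window[1]:.3g}]")
```

prints the robust partitions found across the Markov-time sweep:

```
c= 2  plateau= 51 grid pts  t=[0.955, 100]
c= 3  plateau= 17 grid pts  t=[0.196, 0.87]
c= 4  plateau=  7 grid pts  t=[0.102, 0.179]
c= 7  plateau=  6 grid pts  t=[0.0368, 0.0586]
```

i.e. a coarse 2-way split (distributed versus massed learning) that
persists over two decades of Markov time, and a finer 4-way partition.
Scoring the 4-way candidate against the planted labels and profiling
its clusters:

```python
truth = np.array([cohort.labels[s.learner_id] for s in series])
four = next(c for c in model.report_.candidates if c.n_communities == 4)
print(tc.score_against_truth(four.labels, truth))
for p in tc.cluster_profiles(series, four.labels, n_restarts=1):
    print(p.cluster, round(p.mean_massed_session_length, 2),
          round(p.completion_fraction, 2))
```

```
{'ari': 1.0, 'vi': 0.0}
0 1.77 0.95      # early birds
1 1.70 0.95      # on time
2 1.91 0.86      # low engagers
3 43.63 0.70     # crammers
```

The 4-way partition recovers the planted archetypes exactly
(adjusted Rand index 1.0). Crammers stand out with massed sessions of
~44 tasks and the lowest completion fraction; the Bayes factor for
per-cluster versus pooled Gaussian processes on the same run is
`log K ≈ 2154`, strong evidence that the clusters follow distinct
engagement processes.

The same pipeline is available from the shell:

```sh
tempoclust run --out-dir demo --seed 0       # simulate + full pipeline
tempoclust simulate --n-tasks 376 --seed 0   # or stage by stage
tempoclust similarity events.csv
```

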