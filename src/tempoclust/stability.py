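"""Multiscale graph partitioning by Markov Stability.

A continuous-time random walk p(t) = p(0) e^{-tL} on the learner graph
(L = D - A, the combinatorial Laplacian) probes community structure at
every scale: the quality of a partition, encoded by the 0/1 membership
matrix H, at Markov time t is the trace of the block autocovariance

    R(t; H) = H^T (Pi e^{-tL} - pi^T pi) H,       Pi = diag(pi),

i.e. the probability that a walker started in a community is still
there at time t, in excess of chance.  The Markov Stability of H is
r(t, H) = min_{tau <= t} Tr R(tau; H), maximised over partitions at
each t with a greedy Louvain-style algorithm restarted from shuffled
node orders.  Small t favours fine partitions, large t coarse ones.

Robust scales are selected with the normalised variation of
information: partitions that are reproducible across optimiser restarts
(dips of VI(t)) and persistent across Markov time (low-VI(t, t')
diagonal blocks) are reported as candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from sklearn.base import BaseEstimator, ClusterMixin

from .graph import LearnerGraph

logger = logging.getLogger(__name__)

__all__ = [
    "relabel",
    "variation_of_information",
    "vi_ensemble",
    "block_autocovariance",
    "stability",
    "louvain_optimise",
    "MSScan",
    "scan_markov_times",
    "RobustCandidate",
    "RobustPartitionReport",
    "select_robust_partitions",
    "MarkovStabilityClustering",
]


# ---------------------------------------------------------------------------
# partitions and the variation of information


def relabel(labels: np.ndarray) -> np.ndarray:
    """Canonical form: community ids renumbered by first appearance."""
    labels = np.asarray(labels)
    _, canon = np.unique(labels, return_inverse=True)
    # np.unique sorts by value; re-map to order of first appearance
    first = {}
    out = np.empty(labels.size, dtype=np.int64)
    nxt = 0
    for idx, lab in enumerate(canon):
        if lab not in first:
            first[lab] = nxt
            nxt += 1
        out[idx] = first[lab]
    return out


def _entropy(counts: np.ndarray, n: int) -> float:
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def variation_of_information(p1, p2) -> float:
    """Normalised variation of information between two partitions.

    VI(H, H') = (2 Omega(H, H') - Omega(H) - Omega(H')) / log N, with
    Omega the Shannon entropy of the community relative frequencies and
    Omega(H, H') the joint entropy.  A metric on partitions, 0 iff the
    partitions are identical up to relabelling, and at most 1.
    """
    a = np.asarray(p1).ravel()
    b = np.asarray(p2).ravel()
    if a.size != b.size:
        raise ValueError("partitions must cover the same elements")
    n = a.size
    if n < 2:
        raise ValueError("VI undefined for a single element (log N = 0)")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    na, nb = ai.max() + 1, bi.max() + 1
    joint = np.bincount(ai * nb + bi, minlength=na * nb)
    h_joint = _entropy(joint, n)
    h_a = _entropy(np.bincount(ai), n)
    h_b = _entropy(np.bincount(bi), n)
    return max(0.0, (2.0 * h_joint - h_a - h_b) / np.log(n))


def vi_ensemble(partitions) -> float:
    """Mean pairwise VI over an ensemble of optimised partitions.

    Empty pair sum (a single partition) is defined as 0.  Identical
    partitions are grouped first so the cost scales with the number of
    distinct solutions, not the ensemble size.
    """
    parts = [np.asarray(p) for p in partitions]
    ell = len(parts)
    if ell == 0:
        raise ValueError("empty ensemble")
    if ell == 1:
        return 0.0
    groups: dict[tuple, list[int, np.ndarray]] = {}
    for p in parts:
        key = tuple(relabel(p))
        if key in groups:
            groups[key][0] += 1
        else:
            groups[key] = [1, p]
    uniq = list(groups.values())
    total = 0.0
    for i, (ci, pi_) in enumerate(uniq):
        for cj, pj in uniq[i + 1:]:
            total += 2.0 * ci * cj * variation_of_information(pi_, pj)
    return total / (ell * (ell - 1))


# ---------------------------------------------------------------------------
# diffusion operators


class _Propagator:
    """Spectral cache for e^{-tL} and the generalized modularity matrix.

    L is symmetric, so e^{-tL} = V diag(e^{-t w}) V^T from one
    eigendecomposition, reused across the whole Markov-time grid.
    """

    def __init__(self, graph: LearnerGraph):
        self.pi = graph.pi
        w, v = eigh(graph.laplacian)
        self._w = np.clip(w, 0.0, None)  # L is PSD; clip fp negatives
        self._v = v

    def expm(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError(f"Markov time must be nonnegative, got {t}")
        return (self._v * np.exp(-t * self._w)) @ self._v.T

    def modularity_matrix(self, t: float) -> np.ndarray:
        """B(t) = Pi e^{-tL} - pi^T pi (symmetrised for uniform pi)."""
        pi = self.pi
        b = pi[:, None] * self.expm(t) - np.outer(pi, pi)
        return 0.5 * (b + b.T)


def _membership(labels: np.ndarray) -> np.ndarray:
    labels = relabel(labels)
    c = labels.max() + 1
    h = np.zeros((labels.size, c))
    h[np.arange(labels.size), labels] = 1.0
    return h


def block_autocovariance(graph: LearnerGraph, labels, t: float,
                         _prop: _Propagator | None = None) -> np.ndarray:
    """The c x c block autocovariance R(t; H) of a partition."""
    prop = _prop if _prop is not None else _Propagator(graph)
    h = _membership(np.asarray(labels))
    return h.T @ prop.modularity_matrix(t) @ h


def stability(graph: LearnerGraph, labels, t: float, tau_grid,
              _prop: _Propagator | None = None) -> float:
    """Markov Stability r(t, H): min over grid times tau <= t of Tr R(tau; H).

    The grid stands in for the continuum minimisation; at the first grid
    point (no tau strictly below t) tau = t itself is used.
    """
    tau_grid = np.asarray(tau_grid, dtype=float)
    if tau_grid.size == 0:
        raise ValueError("empty tau grid")
    taus = tau_grid[tau_grid <= t]
    if taus.size == 0:
        taus = np.array([t])
    prop = _prop if _prop is not None else _Propagator(graph)
    same = None
    best = np.inf
    lab = np.asarray(labels)
    same = lab[:, None] == lab[None, :]
    for tau in taus:
        tr = float(np.sum(prop.modularity_matrix(tau) * same))
        if tr < best:
            best = tr
    return best


# ---------------------------------------------------------------------------
# greedy optimisation (Louvain-style on the generalized modularity matrix)


def _louvain_dense(b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One Louvain run maximising sum_{ij in same community} B_ij.

    Node-moving passes to a local optimum, then community aggregation,
    repeated until no move improves.  Dense B; ties go to the lower
    community id (argmax picks the first maximum).
    """
    n = b.shape[0]
    mapping = np.arange(n)
    while True:
        nb = b.shape[0]
        labels = np.arange(nb)
        improved_level = False
        for _ in range(100):  # pass cap per level
            moved = False
            for i in rng.permutation(nb):
                w = np.bincount(labels, weights=b[i], minlength=labels.max() + 1)
                a = labels[i]
                w[a] -= b[i, i]  # own-community score excludes i itself
                best = int(np.argmax(w))
                if w[best] > w[a] + 1e-12 and best != a:
                    labels[i] = best
                    moved = True
                    improved_level = True
            if not moved:
                break
        labels = relabel(labels)
        mapping = labels[mapping]
        if not improved_level:
            return relabel(mapping)
        c = labels.max() + 1
        if c == b.shape[0]:  # nothing merged
            return relabel(mapping)
        h = np.zeros((b.shape[0], c))
        h[np.arange(b.shape[0]), labels] = 1.0
        b = h.T @ b @ h


def louvain_optimise(graph: LearnerGraph, t: float, seed: int = 0,
                     _prop: _Propagator | None = None) -> np.ndarray:
    """Greedy maximisation of Tr[H^T B(t) H] at one Markov time.

    Returns the label vector of a local maximiser; identical seeds give
    identical partitions.
    """
    if not t > 0:
        raise ValueError(f"Markov time must be positive, got {t}")
    prop = _prop if _prop is not None else _Propagator(graph)
    b = prop.modularity_matrix(t)
    rng = np.random.default_rng(seed)
    return _louvain_dense(b, rng)


# ---------------------------------------------------------------------------
# the Markov-time scan


@dataclass
class MSScan:
    """Result of a full Markov-time sweep."""

    t_grid: np.ndarray
    best_labels: np.ndarray  # (n_t, N)
    stability: np.ndarray  # r*(t)
    n_communities: np.ndarray  # c(t)
    vi_t: np.ndarray  # VI(t): optimiser-consistency curve
    vi_cross: np.ndarray  # VI(t, t'): persistence heatmap
    ensembles: list = field(repr=False)  # per t: (ell, N) label arrays
    n_restarts: int = 100
    seed: int = 0
    pi_mode: str = "uniform"

    @property
    def n_t(self) -> int:
        return self.t_grid.size


def default_t_grid(t_min: float = 1e-2, t_max: float = 1e2,
                   n_t: int = 100) -> np.ndarray:
    return np.logspace(np.log10(t_min), np.log10(t_max), n_t)


def scan_markov_times(graph: LearnerGraph, t_grid=None, n_restarts: int = 100,
                      seed: int = 0) -> MSScan:
    """Optimise partitions over a Markov-time grid with restart ensembles.

    Per grid time t the Louvain optimisation is run ``n_restarts`` times
    from seeds derived from ``seed``; each solution is scored by the
    Markov Stability and the argmax kept as the best partition at t.
    VI(t) measures consistency across the ensemble; VI(t, t') compares
    best partitions across times.

    Restart candidates at a given t are ranked by Tr R(t; H): for the
    combinatorial-Laplacian dynamics with uniform stationary measure the
    trace is non-increasing in t for fixed H (all spectral coefficients
    of Tr H^T Pi e^{-tL} H are nonnegative), so the min over tau <= t is
    attained at tau = t.  With a degree-weighted measure the min is
    evaluated on the grid explicitly.
    """
    t_grid = default_t_grid() if t_grid is None else np.asarray(t_grid, float)
    if t_grid.size == 0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be non-empty and strictly increasing")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")

    prop = _Propagator(graph)
    uniform_pi = graph.pi_mode == "uniform"
    n = graph.n_nodes
    n_t = t_grid.size
    rng_seeds = np.random.SeedSequence(seed).spawn(n_t)

    mods = [prop.modularity_matrix(t) for t in t_grid]

    best_labels = np.empty((n_t, n), dtype=np.int64)
    r_star = np.empty(n_t)
    vi_t = np.empty(n_t)
    ensembles = []

    for it, t in enumerate(t_grid):
        b = mods[it]
        child = rng_seeds[it].spawn(n_restarts)
        ens = np.empty((n_restarts, n), dtype=np.int64)
        scores = np.empty(n_restarts)
        seen: dict[tuple, float] = {}
        for r in range(n_restarts):
            lab = _louvain_dense(b, np.random.default_rng(child[r]))
            ens[r] = lab
            key = tuple(lab)
            if key not in seen:
                same = lab[:, None] == lab[None, :]
                if uniform_pi:
                    seen[key] = float(np.sum(b * same))
                else:
                    seen[key] = min(
                        float(np.sum(mods[j] * same)) for j in range(it + 1)
                    )
            scores[r] = seen[key]
        best = int(np.argmax(scores))
        lab = ens[best]
        best_labels[it] = lab
        same = lab[:, None] == lab[None, :]
        # r*(t) via the literal grid min, so it agrees with stability()
        r_star[it] = min(float(np.sum(mods[j] * same)) for j in range(it + 1))
        vi_t[it] = vi_ensemble(ens)
        ensembles.append(ens)
        logger.debug("t=%.4g: c=%d r*=%.4g VI=%.4g", t, lab.max() + 1,
                     r_star[it], vi_t[it])

    vi_cross = np.zeros((n_t, n_t))
    for i in range(n_t):
        for j in range(i + 1, n_t):
            vi_cross[i, j] = vi_cross[j, i] = variation_of_information(
                best_labels[i], best_labels[j])

    return MSScan(
        t_grid=t_grid,
        best_labels=best_labels,
        stability=r_star,
        n_communities=best_labels.max(axis=1) + 1,
        vi_t=vi_t,
        vi_cross=vi_cross,
        ensembles=ensembles,
        n_restarts=n_restarts,
        seed=seed,
        pi_mode=graph.pi_mode,
    )


# ---------------------------------------------------------------------------
# robust-scale selection


@dataclass
class RobustCandidate:
    t_window: tuple[float, float]
    t_selected: float
    labels: np.ndarray
    n_communities: int
    vi_dip_depth: float
    plateau_length: int


@dataclass
class RobustPartitionReport:
    candidates: list[RobustCandidate]
    theta_plateau: float
    l_min: int
    containment: list[float] = field(default_factory=list)

    def best(self) -> RobustCandidate | None:
        return self.candidates[0] if self.candidates else None


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or y.size < window:
        return y
    kernel = np.ones(window) / window
    pad = window // 2
    yp = np.pad(y, pad, mode="edge")
    return np.convolve(yp, kernel, mode="valid")[: y.size]


def _containment(fine: np.ndarray, coarse: np.ndarray) -> float:
    """Fraction of nodes whose fine community maps into a single coarse one."""
    score = 0
    for c in np.unique(fine):
        members = coarse[fine == c]
        score += np.bincount(members).max()
    return score / fine.size


def select_robust_partitions(scan: MSScan, theta_plateau: float = 0.1,
                             l_min: int = 5,
                             smooth_window: int = 3) -> RobustPartitionReport:
    """Select partitions that are persistent across Markov time.

    Contiguous runs of the grid where the community count c(t) is
    constant and the off-diagonal mean of the VI(t, t') block is below
    ``theta_plateau`` become candidates if at least ``l_min`` grid
    points long.  Within each block the partition at the t minimising
    the (window-smoothed) VI(t) is returned; candidates are ranked by
    plateau length, then by the depth of the VI(t) dip.  An empty
    candidate list signals a lack of natural clusters.
    """
    n_t = scan.n_t
    c = scan.n_communities
    vi_s = _smooth(scan.vi_t, smooth_window)

    runs = []
    start = 0
    for i in range(1, n_t + 1):
        if i == n_t or c[i] != c[start]:
            runs.append((start, i))
            start = i

    candidates = []
    for a, b in runs:
        length = b - a
        if length < l_min:
            continue
        block = scan.vi_cross[a:b, a:b]
        off = block[~np.eye(length, dtype=bool)]
        block_mean = float(off.mean()) if off.size else 0.0
        if block_mean >= theta_plateau:
            continue
        local = vi_s[a:b]
        sel = a + int(np.argmin(local))
        dip = float(local.mean() - local.min())
        candidates.append(RobustCandidate(
            t_window=(float(scan.t_grid[a]), float(scan.t_grid[b - 1])),
            t_selected=float(scan.t_grid[sel]),
            labels=scan.best_labels[sel].copy(),
            n_communities=int(c[sel]),
            vi_dip_depth=dip,
            plateau_length=length,
        ))

    candidates.sort(key=lambda x: (-x.plateau_length, -x.vi_dip_depth))
    if not candidates:
        logger.warning("no robust partition found: the scan shows no "
                       "persistent low-VI plateau (no natural clusters)")

    # quasi-hierarchy is reported, not asserted: containment of each
    # finer candidate in the next coarser one, in order of granularity
    by_c = sorted(candidates, key=lambda x: -x.n_communities)
    containment = [
        _containment(by_c[i].labels, by_c[i + 1].labels)
        for i in range(len(by_c) - 1)
    ]
    return RobustPartitionReport(candidates, theta_plateau, l_min, containment)


# ---------------------------------------------------------------------------
# estimator


class MarkovStabilityClustering(ClusterMixin, BaseEstimator):
    """Multiscale Markov Stability clustering of a weighted graph.

    ``fit`` takes a symmetric adjacency matrix (or a
    :class:`~tempoclust.graph.LearnerGraph`), sweeps the Markov-time
    grid with restarted greedy optimisation, and selects robust scales;
    ``labels_`` holds the top-ranked robust partition (falling back to
    the most optimiser-consistent partition when no plateau qualifies).

    Parameters
    ----------
    t_min, t_max : float, default=1e-2, 1e2
        Bounds of the log-spaced Markov-time grid.
    n_t : int, default=100
        Number of grid points.
    n_restarts : int, default=100
        Louvain restarts per grid time.
    theta_plateau : float, default=0.1
        VI(t, t') block-mean threshold for persistence.
    l_min : int, default=5
        Minimum plateau length in grid points.
    pi_mode : {'uniform', 'degree'}, default='uniform'
        Stationary-measure convention.
    random_state : int, default=0
        Master seed for the restart streams.
    """

    def __init__(self, t_min: float = 1e-2, t_max: float = 1e2, n_t: int = 100,
                 n_restarts: int = 100, theta_plateau: float = 0.1,
                 l_min: int = 5, pi_mode: str = "uniform",
                 random_state: int = 0):
        self.t_min = t_min
        self.t_max = t_max
        self.n_t = n_t
        self.n_restarts = n_restarts
        self.theta_plateau = theta_plateau
        self.l_min = l_min
        self.pi_mode = pi_mode
        self.random_state = random_state

    def fit(self, X, y=None):
        if isinstance(X, LearnerGraph):
            graph = X
        else:
            graph = LearnerGraph(np.asarray(X, float), pi_mode=self.pi_mode)
        self.graph_ = graph
        grid = default_t_grid(self.t_min, self.t_max, self.n_t)
        self.scan_ = scan_markov_times(graph, grid,
                                       n_restarts=self.n_restarts,
                                       seed=self.random_state)
        self.report_ = select_robust_partitions(
            self.scan_, theta_plateau=self.theta_plateau, l_min=self.l_min)
        top = self.report_.best()
        if top is not None:
            self.labels_ = top.labels
            self.t_selected_ = top.t_selected
        else:
            sel = int(np.argmin(self.scan_.vi_t))
            self.labels_ = self.scan_.best_labels[sel].copy()
            self.t_selected_ = float(self.scan_.t_grid[sel])
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
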