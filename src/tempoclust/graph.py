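"""Similarity-graph construction by Relaxed Minimum Spanning Tree pruning.

The dense DTW similarity matrix is the adjacency of a complete weighted
graph; most of its edges are redundant and wash out the multiscale
community structure.  RMST keeps the minimum spanning tree of the DTW
*distance* matrix (global connectivity) plus every edge (i, j) that is
not much longer than the bottleneck of the MST path between i and j:

    keep (i, j)  iff  d_ij < mlink_ij + gamma * (d_i^(k) + d_j^(k)),

where ``mlink_ij`` is the largest edge weight on the unique MST path
between i and j, ``d_i^(k)`` is the distance from i to its k-th nearest
neighbour (a local noise scale) and ``gamma`` sets the relaxation
strength.  Edge weights in the resulting learner graph are the kernel
similarities, so sparsification semantics live in distance space while
the diffusion dynamics downstream run on similarities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "minimum_spanning_tree",
    "rmst_sparsify",
    "LearnerGraph",
    "build_graph",
    "RMSTGraph",
]


def _check_distance_matrix(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.all(np.isfinite(d)):
        raise ValueError("distance matrix contains non-finite entries")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    return d


def minimum_spanning_tree(dist: np.ndarray) -> list[tuple[int, int]]:
    """Kruskal MST of a dense symmetric distance matrix.

    Ties are broken lexicographically on (distance, min id, max id) so
    the tree is deterministic even with repeated distances.  Returns the
    N-1 edges as (i, j) pairs with i < j.
    """
    d = _check_distance_matrix(dist)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least two nodes")
    iu, ju = np.triu_indices(n, k=1)
    order = np.lexsort((ju, iu, d[iu, ju]))

    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    edges: list[tuple[int, int]] = []
    for e in order:
        i, j = int(iu[e]), int(ju[e])
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            edges.append((i, j))
            if len(edges) == n - 1:
                break
    return edges


def _mlink_matrix(dist: np.ndarray, mst_edges: list[tuple[int, int]]) -> np.ndarray:
    """Max edge weight on the MST path between every pair (minimax distance).

    Processing MST edges in ascending weight and merging components:
    the edge that first joins the components of i and j is exactly the
    bottleneck of their tree path.
    """
    n = dist.shape[0]
    mlink = np.zeros((n, n))
    comps: dict[int, list[int]] = {i: [i] for i in range(n)}
    comp_of = list(range(n))
    for i, j in sorted(mst_edges, key=lambda e: dist[e[0], e[1]]):
        w = dist[i, j]
        ci, cj = comp_of[i], comp_of[j]
        a, b = comps[ci], comps[cj]
        mlink[np.ix_(a, b)] = w
        mlink[np.ix_(b, a)] = w
        for node in b:
            comp_of[node] = ci
        a.extend(b)
        del comps[cj]
    return mlink


def rmst_sparsify(dist: np.ndarray, gamma: float = 0.5, k: int = 1) -> np.ndarray:
    """Boolean edge mask from the relaxed-MST rule.

    All MST edges are kept, guaranteeing connectivity; the mask is
    symmetric with a False diagonal and monotone in ``gamma``.
    """
    d = _check_distance_matrix(dist)
    n = d.shape[0]
    if gamma < 0:
        raise ValueError(f"gamma must be nonnegative, got {gamma}")
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, N-1]={n - 1}, got {k}")

    mst_edges = minimum_spanning_tree(d)
    mlink = _mlink_matrix(d, mst_edges)

    # d_i^(k): k-th nearest neighbour distance, self excluded
    off = d + np.diag(np.full(n, np.inf))
    dk = np.sort(off, axis=1)[:, k - 1]

    mask = d < mlink + gamma * (dk[:, None] + dk[None, :])
    np.fill_diagonal(mask, False)
    mask &= mask.T
    for i, j in mst_edges:
        mask[i, j] = mask[j, i] = True
    return mask


@dataclass(frozen=True)
class LearnerGraph:
    """Weighted learner similarity graph and its diffusion operators.

    ``adjacency`` is symmetric with zero diagonal; derived operators are
    the degree matrix D = diag(A 1), combinatorial Laplacian L = D - A,
    random-walk transition matrix Q = D^-1 A and a stationary measure
    pi (uniform by default, matching the continuous diffusion e^{-tL}
    whose left null vector is uniform; degree-proportional optionally).
    """

    adjacency: np.ndarray = field(repr=False)
    learner_ids: tuple[str, ...] = ()
    pi_mode: str = "uniform"

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            a = a.copy()
            np.fill_diagonal(a, 0.0)
        if np.any(a < 0):
            raise ValueError("edge weights must be nonnegative")
        if self.pi_mode not in ("uniform", "degree"):
            raise ValueError(f"unknown pi_mode {self.pi_mode!r}")
        ids = tuple(self.learner_ids) or tuple(str(i) for i in range(a.shape[0]))
        if len(ids) != a.shape[0]:
            raise ValueError("learner_ids length does not match adjacency")
        object.__setattr__(self, "adjacency", a)
        object.__setattr__(self, "learner_ids", ids)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @property
    def laplacian(self) -> np.ndarray:
        return np.diag(self.degrees) - self.adjacency

    @property
    def transition(self) -> np.ndarray:
        deg = self.degrees
        if np.any(deg <= 0):
            raise ValueError("transition matrix undefined: isolated node")
        return self.adjacency / deg[:, None]

    @property
    def pi(self) -> np.ndarray:
        if self.pi_mode == "degree":
            deg = self.degrees
            return deg / deg.sum()
        n = self.n_nodes
        return np.full(n, 1.0 / n)

    def is_connected(self) -> bool:
        n_comp, _ = connected_components(self.adjacency > 0, directed=False)
        return n_comp == 1

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, lid in enumerate(self.learner_ids):
            g.add_node(i, learner_id=lid)
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        for i, j in zip(ii, jj):
            g.add_edge(int(i), int(j), weight=float(self.adjacency[i, j]))
        return g


def build_graph(mask: np.ndarray, similarity: np.ndarray,
                learner_ids=(), pi_mode: str = "uniform") -> LearnerGraph:
    """Apply an edge mask to a similarity matrix and wrap the operators.

    Raises if the masked graph is disconnected (cannot happen for masks
    produced by :func:`rmst_sparsify`, which always contain the MST).
    """
    mask = np.asarray(mask, dtype=bool)
    sim = np.asarray(similarity, dtype=float)
    if mask.shape != sim.shape:
        raise ValueError("mask and similarity shapes differ")
    if not np.array_equal(mask, mask.T):
        raise ValueError("edge mask must be symmetric")
    a = np.where(mask, sim, 0.0)
    np.fill_diagonal(a, 0.0)
    g = LearnerGraph(a, learner_ids=tuple(learner_ids), pi_mode=pi_mode)
    if not g.is_connected():
        raise ValueError("masked graph is disconnected")
    return g


class RMSTGraph(TransformerMixin, BaseEstimator):
    """RMST sparsification as a transformer.

    ``fit(D, similarity=A)`` sparsifies the distance matrix ``D`` and
    builds the learner graph weighted by ``A`` (falls back to the
    implied Gaussian similarity of the median bandwidth when ``A`` is
    omitted).

    Parameters
    ----------
    gamma : float, default=0.5
        Relaxation strength; 0 keeps little beyond the MST, large gamma
        approaches the complete graph.
    k : int, default=1
        Neighbour index of the local scale term d_i^(k).
    pi_mode : {'uniform', 'degree'}, default='uniform'
        Stationary measure convention passed to the graph.

    Attributes
    ----------
    mask_ : ndarray of bool, shape (N, N)
    graph_ : LearnerGraph
    """

    def __init__(self, gamma: float = 0.5, k: int = 1, pi_mode: str = "uniform"):
        self.gamma = gamma
        self.k = k
        self.pi_mode = pi_mode

    def fit(self, X, y=None, similarity=None, learner_ids=()):
        d = _check_distance_matrix(X)
        if similarity is None:
            from .dtw import median_bandwidth

            similarity = np.exp(-d / median_bandwidth(d) ** 2)
        self.mask_ = rmst_sparsify(d, gamma=self.gamma, k=self.k)
        self.graph_ = build_graph(self.mask_, similarity,
                                  learner_ids=learner_ids, pi_mode=self.pi_mode)
        return self

    def transform(self, X=None):
        return self.graph_.adjacency

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, **fit_params).transform()
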