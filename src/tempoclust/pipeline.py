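"""End-to-end estimator: trajectories in, behavioural clusters out."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .dtw import DTWKernel
from .graph import RMSTGraph
from .stability import MarkovStabilityClustering

__all__ = ["TemporalEngagementClusterer"]


class TemporalEngagementClusterer(ClusterMixin, BaseEstimator):
    """DTW-kernel similarity -> RMST graph -> Markov Stability clusters.

    ``fit`` accepts a cohort of trajectories (:class:`EventSeries` or
    plain 1-D arrays of completion days) and chains the three stages;
    the fitted sub-estimators are exposed as ``kernel_``, ``grapher_``
    and ``clusterer_`` so intermediate matrices remain inspectable.

    Parameters mirror the stage estimators; see
    :class:`~tempoclust.dtw.DTWKernel`,
    :class:`~tempoclust.graph.RMSTGraph` and
    :class:`~tempoclust.stability.MarkovStabilityClustering`.
    """

    def __init__(self, sigma: float | None = None,
                 sigma_rule: str = "median_distance",
                 gamma: float = 0.5, k: int = 1,
                 t_min: float = 1e-2, t_max: float = 1e2, n_t: int = 100,
                 n_restarts: int = 100, theta_plateau: float = 0.1,
                 l_min: int = 5, pi_mode: str = "uniform",
                 random_state: int = 0):
        self.sigma = sigma
        self.sigma_rule = sigma_rule
        self.gamma = gamma
        self.k = k
        self.t_min = t_min
        self.t_max = t_max
        self.n_t = n_t
        self.n_restarts = n_restarts
        self.theta_plateau = theta_plateau
        self.l_min = l_min
        self.pi_mode = pi_mode
        self.random_state = random_state

    def fit(self, X, y=None):
        series = list(X)
        self.kernel_ = DTWKernel(sigma=self.sigma, sigma_rule=self.sigma_rule)
        sim = self.kernel_.fit_transform(series)
        self.grapher_ = RMSTGraph(gamma=self.gamma, k=self.k,
                                  pi_mode=self.pi_mode)
        self.grapher_.fit(self.kernel_.distances_, similarity=sim,
                          learner_ids=self.kernel_.learner_ids_)
        self.clusterer_ = MarkovStabilityClustering(
            t_min=self.t_min, t_max=self.t_max, n_t=self.n_t,
            n_restarts=self.n_restarts, theta_plateau=self.theta_plateau,
            l_min=self.l_min, pi_mode=self.pi_mode,
            random_state=self.random_state)
        self.clusterer_.fit(self.grapher_.graph_)
        self.labels_ = self.clusterer_.labels_
        self.learner_ids_ = list(self.kernel_.learner_ids_)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    @property
    def scan_(self):
        return self.clusterer_.scan_

    @property
    def report_(self):
        return self.clusterer_.report_

    def labels_by_id(self) -> dict[str, int]:
        return dict(zip(self.learner_ids_, (int(l) for l in self.labels_)))

    def robust_partitions(self) -> list[np.ndarray]:
        return [c.labels for c in self.clusterer_.report_.candidates]
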