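"""Post-hoc statistical characterisation of behavioural clusters.

Once robust clusters are found, each is profiled by interpretable
statistics: the mean massed-session length (run lengths of the isotonic
fit of completion time against task order — plateaux are bursts of
tasks finished together), the task-completion fraction, and an average
engagement trajectory estimated by Gaussian-process regression on the
pooled cumulative task counts of the cluster's members.  Differences
between clusters are quantified by a Bayes factor comparing per-cluster
Gaussian processes against a single pooled process, low/high-performer
over-representation by an upper-tail hypergeometric test, and a
feature-based classifier baseline (RBF-SVM and a depth-4 decision tree
on z-scored features) is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.isotonic import IsotonicRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .series import EventSeries

__all__ = [
    "IsotonicFit",
    "isotonic_fit",
    "mean_massed_session_length",
    "completion_fraction",
    "gpr_cluster_trajectory",
    "BayesComparison",
    "bayes_factor",
    "enrichment_pvalue",
    "baseline_classify",
    "ClusterProfile",
    "cluster_profiles",
]

# grade banding: below "Merit" / "Distinction" thresholds
LOW_GRADE = 60.0
HIGH_GRADE = 70.0


@dataclass(frozen=True)
class IsotonicFit:
    """Least-squares non-decreasing fit of a vector.

    ``x`` is the unique minimiser of ||y - x||^2 subject to
    x_0 <= x_1 <= ... <= x_n (pool-adjacent-violators solution);
    ``blocks`` lists the constant segments as (start, end, level) with
    end exclusive.
    """

    y: np.ndarray
    x: np.ndarray
    blocks: tuple[tuple[int, int, float], ...]


def isotonic_fit(y) -> IsotonicFit:
    """Exact least-squares isotonic (non-decreasing) regression."""
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size == 0:
        raise ValueError("input must be a non-empty 1-D vector")
    if not np.all(np.isfinite(y)):
        raise ValueError("input contains non-finite values")
    iso = IsotonicRegression(increasing=True)
    x = iso.fit_transform(np.arange(y.size), y)
    blocks = []
    start = 0
    for i in range(1, y.size + 1):
        if i == y.size or not np.isclose(x[i], x[start], rtol=0, atol=1e-12):
            blocks.append((start, i, float(x[start])))
            start = i
    return IsotonicFit(y=y, x=x, blocks=tuple(blocks))


def mean_massed_session_length(series: EventSeries | np.ndarray,
                               tol_days: float = 0.0) -> float:
    """Mean number of tasks per massed session.

    The completion times (ordered by task index) are first made
    monotone by isotonic regression — out-of-order completions fold
    into plateaux rather than breaking them — then maximal runs of
    consecutive tasks whose fitted times differ by at most ``tol_days``
    are counted as sessions.  Singleton sessions are included, so a
    perfectly spread-out learner scores 1.0.
    """
    times = series.times if isinstance(series, EventSeries) else np.asarray(series, float)
    if times.size == 0:
        raise ValueError("empty trajectory")
    if tol_days < 0:
        raise ValueError("tol_days must be nonnegative")
    x = isotonic_fit(times).x
    sessions = []
    run = 1
    for i in range(1, x.size):
        if x[i] - x[i - 1] <= tol_days + 1e-12:
            run += 1
        else:
            sessions.append(run)
            run = 1
    sessions.append(run)
    return float(np.mean(sessions))


def completion_fraction(series: EventSeries) -> float:
    """Fraction of curriculum tasks the learner completed."""
    if series.n_total_tasks < 1:
        raise ValueError("n_total_tasks must be >= 1")
    if len(series) > series.n_total_tasks:
        raise ValueError("more completions than tasks")
    return len(series) / series.n_total_tasks


# ---------------------------------------------------------------------------
# Gaussian-process trajectories and Bayes factors


def _pool_observations(members, max_points_per_member: int | None = None,
                       max_total_points: int = 400):
    # cubic-cost GP: cap the pooled design size, thinning each member's
    # cumulative curve evenly when the cohort is large
    if max_total_points:
        per_member_cap = max(4, max_total_points // max(len(members), 1))
        if max_points_per_member is None:
            max_points_per_member = per_member_cap
        else:
            max_points_per_member = min(max_points_per_member, per_member_cap)
    xs, ys = [], []
    for m in members:
        days, cum = m.cumulative() if isinstance(m, EventSeries) else m
        days = np.asarray(days, float)
        cum = np.asarray(cum, float)
        if max_points_per_member and days.size > max_points_per_member:
            idx = np.linspace(0, days.size - 1, max_points_per_member).round().astype(int)
            days, cum = days[idx], cum[idx]
        xs.append(days)
        ys.append(cum)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    order = np.argsort(x, kind="stable")
    return x[order, None], y[order]


def _fit_gpr(x, y, n_restarts: int = 5, random_state: int = 0,
             kernel=None, optimize: bool = True) -> GaussianProcessRegressor:
    if kernel is None:
        span = max(x.max() - x.min(), 1.0)
        kernel = (ConstantKernel(1.0, (1e-3, 1e4))
                  * RBF(length_scale=span / 4,
                        length_scale_bounds=(span / 100, span * 10))
                  + WhiteKernel(noise_level=1.0, noise_level_bounds=(1e-6, 1e4)))
    gpr = GaussianProcessRegressor(
        kernel=kernel,
        optimizer="fmin_l_bfgs_b" if optimize else None,
        n_restarts_optimizer=n_restarts if optimize else 0,
        normalize_y=True,
        random_state=random_state,
    )
    gpr.fit(x, y)
    return gpr


def gpr_cluster_trajectory(members, grid, n_restarts: int = 5,
                           random_state: int = 0,
                           max_points_per_member: int | None = 60):
    """Average engagement trajectory of a cluster by GP regression.

    Members' cumulative task counts versus day are pooled and fitted
    with a squared-exponential plus observation-noise covariance, with
    hyperparameters set by maximising the log marginal likelihood.

    Returns ``(mean, variance, log_marginal_likelihood)`` with mean and
    pointwise variance evaluated on ``grid`` (days).
    """
    members = list(members)
    if not members:
        raise ValueError("empty member list")
    x, y = _pool_observations(members, max_points_per_member)
    if x.shape[0] < 2:
        raise ValueError("need at least two observations for a GP trajectory")
    gpr = _fit_gpr(x, y, n_restarts=n_restarts, random_state=random_state)
    grid = np.asarray(grid, float)[:, None]
    mean, std = gpr.predict(grid, return_std=True)
    return mean, std**2, float(gpr.log_marginal_likelihood_value_)


@dataclass(frozen=True)
class BayesComparison:
    """Evidence ratio between per-cluster and pooled trajectory models.

    ``log_K = sum_c logML(cluster c) - logML(pooled)`` under equal model
    priors; K > 1 supports separate per-cluster processes (M1) over one
    pooled process (M2).
    """

    log_K: float
    K: float
    log_ml_clusters: tuple[float, ...]
    log_ml_pooled: float


def bayes_factor(cluster_members: list[list], all_members: list,
                 n_restarts: int = 5, random_state: int = 0,
                 max_points_per_member: int | None = 60,
                 refit_hyperparameters: bool = True) -> BayesComparison:
    """Bayes factor for per-cluster versus pooled Gaussian processes.

    The clusters must partition ``all_members``.  With
    ``refit_hyperparameters=True`` (default) each cluster's GP is
    optimised on its own data; with ``False`` the pooled model's
    hyperparameters are reused when scoring each cluster, isolating the
    data split from hyperparameter flexibility.
    """
    if not cluster_members or any(len(c) == 0 for c in cluster_members):
        raise ValueError("clusters must be non-empty")
    n_assigned = sum(len(c) for c in cluster_members)
    if n_assigned != len(all_members):
        raise ValueError("clusters do not partition the member set")

    xp, yp = _pool_observations(all_members, max_points_per_member)
    pooled = _fit_gpr(xp, yp, n_restarts=n_restarts, random_state=random_state)
    log_ml_pooled = float(pooled.log_marginal_likelihood_value_)

    if len(cluster_members) == 1:
        # identical model on identical data: no separation signal
        return BayesComparison(0.0, 1.0, (log_ml_pooled,), log_ml_pooled)

    logs = []
    for ci, members in enumerate(cluster_members):
        x, y = _pool_observations(members, max_points_per_member)
        if refit_hyperparameters:
            g = _fit_gpr(x, y, n_restarts=n_restarts,
                         random_state=random_state + ci + 1)
        else:
            g = _fit_gpr(x, y, kernel=pooled.kernel_, optimize=False)
        logs.append(float(g.log_marginal_likelihood_value_))

    log_k = float(sum(logs) - log_ml_pooled)
    return BayesComparison(log_k, float(np.exp(np.clip(log_k, -700, 700))),
                           tuple(logs), log_ml_pooled)


# ---------------------------------------------------------------------------
# enrichment and classifier baseline


def enrichment_pvalue(cluster_size: int, cluster_hits: int,
                      population: int, population_hits: int) -> float:
    """Upper-tail hypergeometric P(X >= cluster_hits): the probability
    that a random cluster of the same size contains at least as many
    flagged learners as observed."""
    if not (0 <= cluster_hits <= cluster_size <= population
            and 0 <= population_hits <= population
            and cluster_hits <= population_hits):
        raise ValueError("inconsistent counts")
    return float(hypergeom.sf(cluster_hits - 1, population,
                              population_hits, cluster_size))


def baseline_classify(features: np.ndarray, labels, seed: int = 0):
    """Feature-based classifier baseline (the comparison surface).

    z-scores the feature columns, then trains an SVM with an RBF kernel
    and a depth-4 decision tree; reports per-class counts correctly
    classified on the training data for each model.
    """
    x = np.asarray(features, float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    z = StandardScaler().fit_transform(x)
    out = {}
    for name, model in (("svm_rbf", SVC(kernel="rbf", random_state=seed)),
                        ("decision_tree",
                         DecisionTreeClassifier(max_depth=4, random_state=seed))):
        pred = model.fit(z, y).predict(z)
        per_class = {
            str(c): {"correct": int(np.sum((y == c) & (pred == c))),
                     "total": int(np.sum(y == c))}
            for c in classes
        }
        out[name] = {"model": model,
                     "accuracy": float(np.mean(pred == y)),
                     "per_class": per_class}
    return z, out


# ---------------------------------------------------------------------------
# cluster report


@dataclass
class ClusterProfile:
    cluster: int
    member_ids: list[str]
    mean_massed_session_length: float
    completion_fraction: float
    gpr_mean: np.ndarray = field(repr=False)
    gpr_variance: np.ndarray = field(repr=False)
    log_marginal_likelihood: float = float("nan")


def cluster_profiles(series: list[EventSeries], labels, grid=None,
                     tol_days: float = 0.0, n_restarts: int = 5,
                     random_state: int = 0,
                     min_cluster_size_for_gpr: int = 1) -> list[ClusterProfile]:
    """Profile each cluster: session massing, completion, GP trajectory.

    Learners with no completions contribute a completion fraction of 0
    and are excluded from the session and trajectory statistics.
    """
    labels = np.asarray(labels)
    if labels.size != len(series):
        raise ValueError("labels and series length mismatch")
    if grid is None:
        tmax = max((s.times.max() for s in series if len(s)), default=1.0)
        grid = np.linspace(0.0, float(tmax), 50)
    profiles = []
    for c in np.unique(labels):
        members = [s for s, l in zip(series, labels) if l == c]
        nonempty = [s for s in members if len(s)]
        msl = (float(np.mean([mean_massed_session_length(s, tol_days)
                              for s in nonempty])) if nonempty else float("nan"))
        cf = float(np.mean([completion_fraction(s) for s in members]))
        if len(nonempty) >= min_cluster_size_for_gpr and sum(
                len(s) for s in nonempty) >= 2:
            mean, var, lml = gpr_cluster_trajectory(
                nonempty, grid, n_restarts=n_restarts, random_state=random_state)
        else:
            mean = np.full(len(grid), np.nan)
            var = np.full(len(grid), np.nan)
            lml = float("nan")
        profiles.append(ClusterProfile(
            cluster=int(c),
            member_ids=[s.learner_id for s in members],
            mean_massed_session_length=msl,
            completion_fraction=cf,
            gpr_mean=mean,
            gpr_variance=var,
            log_marginal_likelihood=lml,
        ))
    return profiles
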