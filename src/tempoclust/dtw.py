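"""Dynamic time warping distances and the Gaussian DTW kernel.

The pairwise similarity between two learners' completion-time vectors
``x`` (length n) and ``y`` (length m) is

    k(x, y) = exp(-D(x, y) / sigma^2),

where ``D`` is the unconstrained DTW distance: the minimum, over all
monotone warping paths from cell (1, 1) to (n, m) of the n-by-m local
cost matrix, of the summed squared differences (x_i - y_j)^2 along the
path.  Steps allowed are right, down and diagonal; there is no warping
window and no slope weighting.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .series import EventSeries

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


__all__ = [
    "EmptySeriesError",
    "dtw_distance",
    "dtw_kernel",
    "median_bandwidth",
    "pairwise_similarity",
    "DTWKernel",
]


class EmptySeriesError(ValueError):
    """Raised when a DTW argument has no events.

    Distinguishable from numeric failures so that callers can decide how
    to treat learners with zero completions (e.g. drop them upstream).
    """


@njit(cache=True)
def _dtw_cost(x: np.ndarray, y: np.ndarray) -> float:
    n = x.shape[0]
    m = y.shape[0]
    prev = np.empty(m, dtype=np.float64)
    cur = np.empty(m, dtype=np.float64)
    # first row: only horizontal moves reach (0, j)
    d = x[0] - y[0]
    prev[0] = d * d
    for j in range(1, m):
        d = x[0] - y[j]
        prev[j] = prev[j - 1] + d * d
    for i in range(1, n):
        d = x[i] - y[0]
        cur[0] = prev[0] + d * d
        for j in range(1, m):
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if cur[j - 1] < best:
                best = cur[j - 1]
            d = x[i] - y[j]
            cur[j] = best + d * d
        prev, cur = cur, prev
    return prev[m - 1]


def _as_vector(x) -> np.ndarray:
    if isinstance(x, EventSeries):
        v = x.times
    else:
        v = np.asarray(x, dtype=float)
    if v.ndim != 1:
        raise ValueError("a trajectory must be a one-dimensional vector")
    if v.size == 0:
        raise EmptySeriesError("cannot compute DTW for an empty trajectory")
    if not np.all(np.isfinite(v)):
        raise ValueError("trajectory contains non-finite values")
    return np.ascontiguousarray(v, dtype=np.float64)


def dtw_distance(x, y) -> float:
    """DTW distance between two trajectories (squared-difference cost).

    Symmetric in its arguments and zero iff the two vectors are
    elementwise equal at equal length.  Accepts :class:`EventSeries`
    or plain 1-D arrays.
    """
    return float(_dtw_cost(_as_vector(x), _as_vector(y)))


def dtw_kernel(dist: float, sigma: float) -> float:
    """Map a DTW distance to a similarity in (0, 1] via exp(-d / sigma^2)."""
    if not np.isfinite(dist) or dist < 0:
        raise ValueError(f"distance must be finite and nonnegative, got {dist}")
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return float(np.exp(-dist / sigma**2))


def median_bandwidth(distances: np.ndarray) -> float:
    """Median-heuristic bandwidth: sigma such that sigma^2 is the median
    off-diagonal DTW distance (the median distance then maps to e^-1)."""
    d = np.asarray(distances, float)
    off = d[~np.eye(d.shape[0], dtype=bool)]
    med = float(np.median(off))
    if med <= 0:
        raise ValueError("median off-diagonal distance is not positive; "
                         "all trajectories may be identical")
    return float(np.sqrt(med))


class DTWKernel(TransformerMixin, BaseEstimator):
    """Pairwise DTW-kernel similarity transformer.

    ``fit_transform`` maps a cohort of trajectories to the N x N
    similarity matrix ``A`` with entries exp(-D_ij / sigma^2); the raw
    distance matrix is kept in ``distances_``.

    Parameters
    ----------
    sigma : float or None, default=None
        Kernel bandwidth.  Ignored when ``sigma_rule='median_distance'``.
    sigma_rule : {'median_distance', 'fixed'}, default='median_distance'
        'median_distance' sets sigma^2 to the median off-diagonal DTW
        distance of the fitted cohort; 'fixed' uses ``sigma`` as given.

    Attributes
    ----------
    distances_ : ndarray of shape (N, N)
        Symmetric DTW distance matrix with zero diagonal.
    similarity_ : ndarray of shape (N, N)
        Kernel similarity matrix; unit diagonal, entries in (0, 1].
    sigma_ : float
        Bandwidth actually used.
    learner_ids_ : list of str
        Row/column order of the matrices.
    """

    def __init__(self, sigma: float | None = None,
                 sigma_rule: str = "median_distance"):
        self.sigma = sigma
        self.sigma_rule = sigma_rule

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        series = list(X)
        n = len(series)
        if n < 2:
            raise ValueError("need at least two trajectories")
        ids = [s.learner_id if isinstance(s, EventSeries) else str(i)
               for i, s in enumerate(series)]
        if len(set(ids)) != n:
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate learner ids: {dup}")
        vecs = [_as_vector(s) for s in series]

        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = _dtw_cost(vecs[i], vecs[j])

        if self.sigma_rule == "median_distance":
            sigma = median_bandwidth(d)
        elif self.sigma_rule == "fixed":
            if self.sigma is None or not self.sigma > 0:
                raise ValueError("sigma_rule='fixed' requires positive sigma")
            sigma = float(self.sigma)
        else:
            raise ValueError(f"unknown sigma_rule {self.sigma_rule!r}")

        a = np.exp(-d / sigma**2)
        np.fill_diagonal(a, 1.0)

        self.learner_ids_ = ids
        self.distances_ = d
        self.similarity_ = a
        self.sigma_ = sigma
        return a

    def transform(self, X) -> np.ndarray:
        # stateless pairwise transform: recompute on the given cohort
        return self.fit_transform(X)


def pairwise_similarity(cohort, sigma: float | None = None,
                        sigma_rule: str = "median_distance"):
    """Compute (distance matrix, similarity matrix) for a cohort.

    Thin functional wrapper over :class:`DTWKernel`, returning the pair
    ``(D, A)``; fit the estimator directly if the bandwidth or learner
    order is also needed.
    """
    k = DTWKernel(sigma=sigma, sigma_rule=sigma_rule)
    a = k.fit_transform(cohort)
    return k.distances_, a
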