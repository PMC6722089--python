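import numpy as np
import pytest

import tempoclust as tc

STUDY_ARCHETYPES = ["early_bird", "on_time", "low_engager", "crammer"]


@pytest.fixture(scope="session")
def curriculum():
    """The study-scale curriculum: 376 tasks over three 70-day terms."""
    return tc.make_curriculum(376, 3, 70.0)


@pytest.fixture(scope="session")
def planted_cohort(curriculum):
    """Four archetypes x 20 learners with ground-truth labels, seed 0."""
    specs = [(tc.ARCHETYPES[a], 20) for a in STUDY_ARCHETYPES]
    return tc.simulate_cohort(curriculum, specs, seed=0)


@pytest.fixture(scope="session")
def planted_series(planted_cohort):
    return [s for s in planted_cohort.to_event_series(376) if len(s)]


@pytest.fixture(scope="session")
def planted_truth(planted_cohort, planted_series):
    return np.array([planted_cohort.labels[s.learner_id]
                     for s in planted_series])


@pytest.fixture(scope="session")
def planted_kernel(planted_series):
    return tc.DTWKernel().fit(planted_series)


@pytest.fixture(scope="session")
def fitted_pipeline(planted_series):
    """Full pipeline at default settings (gamma=0.5, 100 Markov times,
    100 restarts); shared across tests since it is the expensive stage."""
    return tc.TemporalEngagementClusterer(random_state=0).fit(planted_series)


@pytest.fixture(scope="session")
def two_clique_graph():
    """Two 4-cliques joined by one weak edge: unambiguous 2-community
    structure at order-1 Markov time."""
    a = np.zeros((8, 8))
    for block in (range(4), range(4, 8)):
        for i in block:
            for j in block:
                if i != j:
                    a[i, j] = 1.0
    a[3, 4] = a[4, 3] = 0.1
    return tc.LearnerGraph(a)


def all_set_partitions(n):
    """All partitions of {0..n-1} as label vectors (restricted growth)."""
    out = []

    def rec(prefix, m):
        if len(prefix) == n:
            out.append(np.array(prefix))
            return
        for v in range(m + 1):
            rec(prefix + [v], max(m, v + 1))

    rec([0], 1)
    return out


def dtw_brute(x, y):
    """Exhaustive enumeration of all monotone warping paths."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n, m = len(x), len(y)
    best = [np.inf]

    def rec(i, j, acc):
        acc = acc + (x[i] - y[j]) ** 2
        if i == n - 1 and j == m - 1:
            best[0] = min(best[0], acc)
            return
        if i + 1 < n:
            rec(i + 1, j, acc)
        if j + 1 < m:
            rec(i, j + 1, acc)
        if i + 1 < n and j + 1 < m:
            rec(i + 1, j + 1, acc)

    rec(0, 0, 0.0)
    return best[0]
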