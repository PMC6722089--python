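from itertools import combinations

import numpy as np
import pytest

import tempoclust as tc
from tempoclust.characterise import _fit_gpr


def brute_isotonic(y):
    """Exact monotone least-squares fit by enumerating every split of
    the sequence into contiguous blocks fitted at their means."""
    y = np.asarray(y, float)
    n = len(y)
    best_sse, best_x = np.inf, None
    for mask in range(1 << (n - 1)):
        bounds = [0] + [i + 1 for i in range(n - 1) if mask >> i & 1] + [n]
        levels = [y[a:b].mean() for a, b in zip(bounds, bounds[1:])]
        if any(b < a for a, b in zip(levels, levels[1:])):
            continue
        x = np.concatenate([np.full(b - a, l) for (a, b), l in
                            zip(zip(bounds, bounds[1:]), levels)])
        sse = np.sum((y - x) ** 2)
        if sse < best_sse:
            best_sse, best_x = sse, x
    return best_x


class TestIsotonic:
    @pytest.mark.parametrize("y, expected", [
        ([1, 2, 3], [1, 2, 3]),
        ([1, 3, 2], [1, 2.5, 2.5]),
        ([3, 2, 1], [2, 2, 2]),
    ])
    def test_known_fits(self, y, expected):
        fit = tc.isotonic_fit(y)
        assert np.allclose(fit.x, expected)

    def test_blocks_structure(self):
        fit = tc.isotonic_fit([1, 3, 2, 5])
        assert fit.blocks == ((0, 1, 1.0), (1, 3, 2.5), (3, 4, 5.0))

    def test_matches_exhaustive_block_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            y = rng.integers(-3, 4, rng.integers(1, 6)).astype(float)
            assert np.allclose(tc.isotonic_fit(y).x, brute_isotonic(y))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tc.isotonic_fit([])


class TestMassedSessionLength:
    def test_spread_out_learner_scores_one(self):
        assert tc.mean_massed_session_length([1.0, 5.0, 9.0, 20.0]) == 1.0

    def test_single_burst(self):
        assert tc.mean_massed_session_length([7.0] * 12) == 12.0

    def test_hand_counted_runs(self):
        times = [1, 2, 10, 10, 10, 20, 20]
        # sessions of sizes {1, 1, 3, 2} -> mean 1.75
        assert tc.mean_massed_session_length(times, tol_days=0.0) == 1.75

    def test_shift_invariance_and_tol_monotonicity(self):
        rng = np.random.default_rng(23)
        times = np.sort(rng.uniform(0, 50, 30))
        base = tc.mean_massed_session_length(times, 0.5)
        assert tc.mean_massed_session_length(times + 17.3, 0.5) == base
        vals = [tc.mean_massed_session_length(times, tol)
                for tol in (0.0, 0.5, 2.0, 10.0)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_out_of_order_times_fold_into_plateaux(self):
        # a decreasing pair pools under the isotonic fit
        assert tc.mean_massed_session_length([1.0, 5.0, 4.0]) == pytest.approx(
            (1 + 2) / 2)


class TestCompletionFraction:
    def test_bounds(self):
        assert tc.completion_fraction(tc.EventSeries("a", np.array([]), 10)) == 0.0
        full = tc.EventSeries("b", np.arange(376, dtype=float), 376)
        assert tc.completion_fraction(full) == 1.0

    def test_crammer_cohort_mean_matches_binomial_expectation(self, curriculum,
                                                              planted_cohort):
        series = planted_cohort.to_event_series(376)
        crammers = [s for s in series
                    if planted_cohort.labels[s.learner_id] == "crammer"]
        mean = np.mean([tc.completion_fraction(s) for s in crammers])
        assert mean == pytest.approx(0.7, abs=0.05)


class TestGPRTrajectory:
    def test_recovers_noiseless_line(self):
        days = np.linspace(0, 100, 20)
        members = [(days, 0.5 * days) for _ in range(3)]
        grid = np.linspace(10, 90, 15)
        mean, var, lml = tc.gpr_cluster_trajectory(members, grid, n_restarts=1)
        assert np.all(var >= 0)
        assert np.allclose(mean, 0.5 * grid, rtol=0.02)

    def test_matches_closed_form_at_fixed_hyperparameters(self):
        # GP posterior mean mu = K*^T (K + s^2 I)^-1 y, computed by hand
        from sklearn.gaussian_process.kernels import RBF, WhiteKernel

        rng = np.random.default_rng(3)
        x = np.sort(rng.uniform(0, 10, 15))[:, None]
        y = np.sin(x).ravel()
        ell, s2 = 2.0, 1e-2
        kern = RBF(ell, "fixed") + WhiteKernel(s2, "fixed")
        g = _fit_gpr(x, y - y.mean(), kernel=kern, optimize=False)
        g.set_params(normalize_y=False)
        g.fit(x, y - y.mean())
        grid = np.linspace(1, 9, 7)[:, None]
        got = g.predict(grid)
        k_xx = np.exp(-0.5 * (x - x.T) ** 2 / ell**2) + s2 * np.eye(15)
        k_sx = np.exp(-0.5 * (grid - x.T) ** 2 / ell**2)
        expect = k_sx @ np.linalg.solve(k_xx, y - y.mean())
        assert np.allclose(got, expect, atol=1e-8)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        days = np.linspace(0, 50, 10)
        members = [(days, days + rng.normal(0, 1, 10)) for _ in range(4)]
        grid = np.linspace(5, 45, 8)
        m1, _, _ = tc.gpr_cluster_trajectory(members, grid, n_restarts=1)
        m2, _, _ = tc.gpr_cluster_trajectory(members[::-1], grid, n_restarts=1)
        assert np.allclose(m1, m2)

    def test_variance_shrinks_with_members(self):
        # at fixed hyperparameters, conditioning on more member
        # trajectories can only reduce the posterior variance
        from sklearn.gaussian_process.kernels import RBF, WhiteKernel

        rng = np.random.default_rng(5)
        days = np.linspace(0, 50, 8)
        members = [(days, days + rng.normal(0, 2, 8)) for _ in range(30)]
        kern = RBF(10.0, "fixed") + WhiteKernel(4.0, "fixed")
        grid = np.linspace(5, 45, 6)[:, None]

        def var_of(sub):
            x = np.concatenate([d for d, _ in sub])[:, None]
            y = np.concatenate([c for _, c in sub])
            g = _fit_gpr(x, y, kernel=kern, optimize=False)
            _, std = g.predict(grid, return_std=True)
            return std**2

        v3, v30 = var_of(members[:3]), var_of(members)
        assert np.all(v3 >= 0) and np.all(v30 >= 0)
        assert np.all(v30 <= v3 + 1e-9)

    def test_empty_members_rejected(self):
        with pytest.raises(ValueError):
            tc.gpr_cluster_trajectory([], np.arange(3.0))


class TestBayesFactor:
    def make_cluster(self, offset, rng, n=5):
        days = np.linspace(0, 100, 10)
        return [(days, 0.5 * days + offset + rng.normal(0, 1, 10))
                for _ in range(n)]

    def test_single_cluster_exactly_zero(self):
        rng = np.random.default_rng(0)
        c = self.make_cluster(0, rng)
        bf = tc.bayes_factor([c], c, n_restarts=1)
        assert bf.log_K == 0.0
        assert bf.K == 1.0

    def test_planted_separation_positive(self):
        rng = np.random.default_rng(1)
        a = self.make_cluster(0, rng)
        b = self.make_cluster(25, rng)
        bf = tc.bayes_factor([a, b], a + b, n_restarts=1)
        assert bf.log_K > 0
        assert bf.K == pytest.approx(np.exp(bf.log_K))

    def test_nested_decomposition_fixed_hyperparameters(self):
        # with shared hyperparameters the evidence is additive over
        # refinements: logK(fine|pooled) = logK(fine|coarse) + logK(coarse|pooled)
        rng = np.random.default_rng(2)
        quarters = [self.make_cluster(o, rng, n=3) for o in (0, 5, 20, 25)]
        coarse = [quarters[0] + quarters[1], quarters[2] + quarters[3]]
        allm = coarse[0] + coarse[1]
        fine_pooled = tc.bayes_factor(quarters, allm,
                                      refit_hyperparameters=False, n_restarts=1)
        coarse_pooled = tc.bayes_factor(coarse, allm,
                                        refit_hyperparameters=False, n_restarts=1)
        fine_c1 = tc.bayes_factor(quarters[:2], coarse[0],
                                  refit_hyperparameters=False, n_restarts=1)
        fine_c2 = tc.bayes_factor(quarters[2:], coarse[1],
                                  refit_hyperparameters=False, n_restarts=1)
        # hyperparameters differ between the pooled fits of different
        # member sets, so compare with the pooled model of the full set
        lhs = fine_pooled.log_K
        rhs = (coarse_pooled.log_K
               + (sum(fine_pooled.log_ml_clusters)
                  - sum(coarse_pooled.log_ml_clusters)))
        assert lhs == pytest.approx(rhs, abs=1e-6)

    def test_bad_partition_rejected(self):
        rng = np.random.default_rng(3)
        c = self.make_cluster(0, rng)
        with pytest.raises(ValueError):
            tc.bayes_factor([c, []], c)
        with pytest.raises(ValueError):
            tc.bayes_factor([c[:2]], c)


class TestEnrichment:
    def test_cluster_equals_population(self):
        assert tc.enrichment_pvalue(20, 5, 20, 5) == pytest.approx(1.0)

    def test_all_hits_in_cluster(self):
        from math import comb

        p = tc.enrichment_pvalue(5, 5, 20, 5)
        assert p == pytest.approx(1 / comb(20, 5))
        assert p == pytest.approx(6.4499e-5, rel=1e-3)

    def test_zero_hits_upper_tail_is_one(self):
        assert tc.enrichment_pvalue(6, 0, 30, 4) == pytest.approx(1.0)

    def test_matches_exact_subset_enumeration(self):
        rng = np.random.default_rng(29)
        for _ in range(20):
            pop = int(rng.integers(4, 13))
            pop_hits = int(rng.integers(1, pop + 1))
            size = int(rng.integers(1, pop + 1))
            hits = int(rng.integers(0, min(size, pop_hits) + 1))
            flags = [1] * pop_hits + [0] * (pop - pop_hits)
            total = count = 0
            for subset in combinations(range(pop), size):
                total += 1
                count += sum(flags[i] for i in subset) >= hits
            assert tc.enrichment_pvalue(size, hits, pop, pop_hits) == \
                pytest.approx(count / total)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            tc.enrichment_pvalue(5, 6, 20, 10)


class TestBaselineClassifier:
    def test_separable_features_perfect_training_accuracy(self):
        rng = np.random.default_rng(31)
        x = np.vstack([rng.normal(0, 0.3, (20, 2)),
                       rng.normal(5, 0.3, (20, 2))])
        y = np.repeat(["low", "high"], 20)
        z, out = tc.baseline_classify(x, y)
        assert out["svm_rbf"]["accuracy"] == 1.0
        assert out["decision_tree"]["accuracy"] == 1.0
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(z.std(axis=0), 1.0, atol=1e-10)

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(37)
        x = rng.normal(0, 1, (60, 2))
        accs = []
        for _ in range(30):
            y = rng.permutation(np.repeat(["a", "b", "c"], 20))
            _, out = tc.baseline_classify(x, y)
            accs.append(out["svm_rbf"]["accuracy"])
        # training accuracy exceeds the 1/3 prior (flexible fit) but must
        # stay far from separable-case performance
        assert 1 / 3 <= np.mean(accs) < 0.95

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            tc.baseline_classify(np.zeros((5, 2)), ["x"] * 5)


class TestClusterProfiles:
    def test_profiles_on_small_cohort(self):
        rng = np.random.default_rng(41)
        series = []
        for i in range(6):
            t = np.sort(rng.uniform(0, 100, 40))
            series.append(tc.EventSeries(f"L{i}", t, 50))
        labels = np.array([0, 0, 0, 1, 1, 1])
        profiles = tc.cluster_profiles(series, labels, n_restarts=1)
        assert [p.cluster for p in profiles] == [0, 1]
        for p in profiles:
            assert 0 <= p.completion_fraction <= 1
            assert p.mean_massed_session_length >= 1.0
            assert np.all(p.gpr_variance >= 0)
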