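import numpy as np
import pytest

from cardreg.likelihoods import (
    CoxFamily,
    RegressionDataset,
    SurvivalDataset,
    build_risk_index,
    concordance_index,
    family_loss,
    get_family,
    neg_log_partial_likelihood,
    neg_log_partial_likelihood_gradient,
    roc_auc,
)
from cardreg.nsopt import fit_smooth
from oracles import (
    auc_by_pairs,
    central_difference_gradient,
    cindex_by_pairs,
    direct_neg_log_partial_likelihood,
)


def _surv(times, events, X=None):
    times = np.asarray(times, dtype=float)
    X = np.zeros((len(times), 2)) if X is None else np.asarray(X, dtype=float)
    return SurvivalDataset(X, times, events)


class TestRiskIndex:
    def test_no_ties_no_censoring(self):
        idx = build_risk_index(_surv([1, 2, 3], [1, 1, 1]))
        assert idx.m == 3
        assert [len(r) for r in idx.risk_sets] == [3, 2, 1]
        assert list(idx.failure_counts) == [1, 1, 1]

    def test_tied_failures(self):
        idx = build_risk_index(_surv([1, 1, 2], [1, 1, 1]))
        assert idx.m == 2
        assert list(idx.failure_counts) == [2, 1]
        assert [len(r) for r in idx.risk_sets] == [3, 1]

    def test_censored_only_in_risk_sets(self):
        idx = build_risk_index(_surv([1, 2, 3], [1, 0, 1]))
        assert idx.m == 2
        assert list(idx.unique_failure_times) == [1, 3]
        assert [len(r) for r in idx.risk_sets] == [3, 1]

    def test_nesting_and_containment(self, random_surv):
        data = random_surv(seed=5, n=30)
        idx = build_risk_index(data)
        for i in range(idx.m - 1):
            assert set(idx.risk_sets[i + 1]) <= set(idx.risk_sets[i])
        for d, r in zip(idx.failure_sets, idx.risk_sets):
            assert set(d) <= set(r)
        assert sum(idx.failure_counts) == data.events.sum()

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="partial likelihood"):
            _surv([1, 2, 3], [0, 0, 0])


class TestPartialLikelihood:
    def test_zero_beta_no_ties(self):
        data = _surv([1, 2, 3], [1, 1, 1], np.random.default_rng(0).standard_normal((3, 2)))
        expected = (2.0 / 3.0) * (np.log(3) + np.log(2))
        assert neg_log_partial_likelihood(np.zeros(2), data) == pytest.approx(expected, abs=1e-12)

    def test_zero_beta_breslow_ties(self):
        data = _surv([1, 1, 2], [1, 1, 1])
        assert neg_log_partial_likelihood(np.zeros(2), data) == pytest.approx(
            (4.0 / 3.0) * np.log(3), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_formula(self, random_surv, seed):
        data = random_surv(seed=seed, n=20, p=4)
        beta = np.random.default_rng(seed + 100).standard_normal(4)
        ours = neg_log_partial_likelihood(beta, data)
        ref = direct_neg_log_partial_likelihood(beta, data.features, data.times, data.events)
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_overflow_safe(self, random_surv):
        data = random_surv(seed=1)
        val = neg_log_partial_likelihood(np.full(4, 300.0), data)
        assert np.isfinite(val)

    @pytest.mark.parametrize("seed", range(3))
    def test_gradient_matches_finite_difference(self, random_surv, seed):
        data = random_surv(seed=seed, n=25, p=4)
        beta = np.random.default_rng(seed).standard_normal(4) * 0.5
        grad = neg_log_partial_likelihood_gradient(beta, data)
        fd = central_difference_gradient(
            lambda b: neg_log_partial_likelihood(b, data), beta
        )
        assert np.allclose(grad, fd, rtol=1e-5, atol=1e-7)

    def test_zero_feature_zero_gradient(self, random_surv):
        data = random_surv(seed=3)
        X = data.features.copy()
        X[:, 2] = 0.0
        data0 = SurvivalDataset(X, data.times, data.events)
        grad = neg_log_partial_likelihood_gradient(np.array([0.3, -0.2, 0.5, 0.1]), data0)
        assert grad[2] == pytest.approx(0.0, abs=1e-14)

    def test_gradient_vanishes_at_mle(self, random_surv):
        data = random_surv(seed=7, n=60, p=3)
        beta_bar = fit_smooth(data, "cox")
        grad = neg_log_partial_likelihood_gradient(beta_bar, data)
        assert np.linalg.norm(grad) < 1e-5

    def test_convexity_probe(self, random_surv, rng):
        data = random_surv(seed=11, n=30)
        for _ in range(20):
            b1 = rng.standard_normal(4)
            b2 = rng.standard_normal(4)
            lam = rng.uniform()
            mid = neg_log_partial_likelihood(lam * b1 + (1 - lam) * b2, data)
            chord = lam * neg_log_partial_likelihood(b1, data) + (
                1 - lam
            ) * neg_log_partial_likelihood(b2, data)
            assert mid <= chord + 1e-9

    def test_invariant_to_time_shift(self, random_surv, rng):
        data = random_surv(seed=13)
        beta = rng.standard_normal(4)
        shifted = SurvivalDataset(data.features, data.times + 5.0, data.events)
        assert neg_log_partial_likelihood(beta, data) == pytest.approx(
            neg_log_partial_likelihood(beta, shifted), rel=1e-12
        )


class TestFamilies:
    def test_logistic_loss_at_zero(self, random_binary):
        data = random_binary(seed=0)
        beta = np.zeros(data.p + 1)
        assert family_loss(beta, data, "logistic") == pytest.approx(np.log(2), abs=1e-12)

    def test_gaussian_perfect_fit(self, rng):
        X = rng.standard_normal((30, 3))
        beta = np.array([1.0, -2.0, 0.5])
        data = RegressionDataset(X, X @ beta)
        assert family_loss(np.concatenate([beta, [0.0]]), data, "gaussian") == pytest.approx(0.0, abs=1e-20)

    def test_logistic_matches_per_sample_sum(self, random_binary, rng):
        data = random_binary(seed=4, n=25)
        beta = rng.standard_normal(data.p + 1) * 0.5
        z = data.features @ beta[:-1] + beta[-1]
        ref = np.mean([np.log1p(np.exp(zi)) - yi * zi for zi, yi in zip(z, data.outcome)])
        assert family_loss(beta, data, "logistic") == pytest.approx(ref, abs=1e-10)

    def test_logistic_rejects_non_binary(self, rng):
        data = RegressionDataset(rng.standard_normal((10, 2)), rng.standard_normal(10))
        with pytest.raises(ValueError, match="binary"):
            family_loss(np.zeros(3), data, "logistic")

    @pytest.mark.parametrize("family", ["logistic", "gaussian"])
    def test_family_gradients_match_fd(self, family, random_binary, rng):
        data = random_binary(seed=9, n=30)
        if family == "gaussian":
            data = RegressionDataset(data.features, rng.standard_normal(data.n))
        fam = get_family(family)
        beta = rng.standard_normal(data.p + 1) * 0.4
        fd = central_difference_gradient(lambda b: fam.loss(b, data), beta)
        assert np.allclose(fam.gradient(beta, data), fd, rtol=1e-5, atol=1e-7)

    def test_unknown_family(self):
        with pytest.raises(ValueError, match="unknown model family"):
            get_family("poisson")


class TestConcordance:
    def test_perfect_ranking(self):
        assert concordance_index([3, 2, 1], [1, 2, 3], [1, 1, 1]) == 1.0

    def test_inverted_ranking(self):
        assert concordance_index([1, 2, 3], [1, 2, 3], [1, 1, 1]) == 0.0

    def test_worked_example_with_ties(self):
        # pairs (1,2) tied risk, (1,3),(1,4),(2,3),(2,4) concordant -> 4.5/5
        c = concordance_index([2, 2, 1, 0], [1, 2, 3, 4], [1, 1, 0, 1])
        assert c == pytest.approx(0.9)

    def test_matches_pair_enumeration(self, rng):
        risk = rng.standard_normal(25)
        times = rng.exponential(1, 25)
        events = (rng.uniform(size=25) > 0.3).astype(int)
        events[0] = 1
        assert concordance_index(risk, times, events) == pytest.approx(
            cindex_by_pairs(risk, times, events)
        )

    def test_no_comparable_pairs(self):
        with pytest.raises(ValueError, match="comparable"):
            concordance_index([1, 2], [5, 5], [1, 1])

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(99)
        times = rng.exponential(1, 4000)
        events = np.ones(4000, dtype=int)
        c = concordance_index(rng.standard_normal(4000), times, events)
        assert abs(c - 0.5) < 0.05


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_constant_scores(self):
        assert roc_auc([1.0, 1.0, 1.0, 1.0], [0, 1, 0, 1]) == 0.5

    def test_matches_pair_count(self, rng):
        scores = rng.integers(0, 5, size=30).astype(float)  # forces ties
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        assert roc_auc(scores, labels) == pytest.approx(auc_by_pairs(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1.0, 2.0], [1, 1])


class TestDatasetValidation:
    def test_negative_times_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            SurvivalDataset(np.zeros((2, 1)), [-1.0, 2.0], [1, 1])

    def test_nonfinite_feature_rejected(self):
        X = np.array([[1.0], [np.nan]])
        with pytest.raises(ValueError, match="row 1"):
            SurvivalDataset(X, [1.0, 2.0], [1, 1])

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            SurvivalDataset(np.zeros((2, 2)), [1.0, 2.0], [1, 1], ("a", "a"))
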