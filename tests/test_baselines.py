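import itertools

import numpy as np
import pytest

from declust.baselines import (
    baseline_cluster,
    clustering_accuracy,
    estimate_fractions_nnls,
    evaluate_recovery,
    quantile_normalize,
    summarize_reports,
    two_step_cancer_profile,
)
from declust.core_model import (
    CompartmentFractions,
    DeclustError,
    ExpressionMatrix,
    SubtypeAssignment,
)
from declust.optimizer import FitState, OptimizerConfig
from declust.simulator import SimulationConfig, simulate_dataset


def _truth_state(ds):
    from declust.core_model import CompartmentProfiles

    profiles = CompartmentProfiles(ds.true_profiles.cancer_profiles,
                                   ds.true_profiles.immune_profile,
                                   ds.true_profiles.stromal_profile,
                                   list(ds.true_profiles.gene_ids))
    return FitState(profiles=profiles, fractions=ds.true_fractions,
                    assignment=ds.true_assignment, objective=0.0)


class TestTwoStepSubtraction:
    def test_exact_algebraic_inversion_at_zero_noise(self, exact_dataset):
        ds = exact_dataset
        cancer = two_step_cancer_profile(ds.observed,
                                         ds.true_profiles.immune_profile,
                                         ds.true_profiles.stromal_profile,
                                         ds.true_fractions, median_match=False)
        labels0 = ds.true_assignment.zero_based()
        expected = ds.true_profiles.cancer_profiles[:, labels0]
        np.testing.assert_allclose(cancer.values, expected, atol=1e-6)

    def test_pure_cancer_returns_observed(self, rng):
        observed = ExpressionMatrix(rng.normal(2, 1, (20, 6)))
        fractions = CompartmentFractions.from_array(np.tile([1.0, 0, 0], (6, 1)))
        out = two_step_cancer_profile(observed, rng.normal(2, 1, 20),
                                      rng.normal(2, 1, 20), fractions,
                                      median_match=False)
        np.testing.assert_allclose(out.values, observed.values, atol=1e-9)

    def test_matches_elementwise_arithmetic_oracle(self, rng):
        G, S = 8, 5
        observed = ExpressionMatrix(rng.normal(2, 1, (G, S)))
        ref_i, ref_s = rng.normal(2, 1, G), rng.normal(2, 1, G)
        frac = CompartmentFractions.from_array(rng.dirichlet([8, 2, 2], S))
        out, meta = two_step_cancer_profile(observed, ref_i, ref_s, frac,
                                            median_match=False,
                                            return_meta=True)
        o_lin = np.exp(observed.values)
        expected = (o_lin - np.exp(ref_i)[:, None] * frac.f_immune
                    - np.exp(ref_s)[:, None] * frac.f_stromal) / frac.f_cancer
        eps = 1e-6 * np.median(o_lin)
        assert meta["n_floored"] == int(np.sum(expected < eps))
        np.testing.assert_allclose(out.values,
                                   np.log(np.clip(expected, eps, None)),
                                   atol=1e-12)

    def test_median_matching_rescales_references(self, rng):
        G, S = 50, 8
        observed = ExpressionMatrix(rng.normal(2, 1, (G, S)))
        ref_i, ref_s = rng.normal(2, 1, G), rng.normal(2, 1, G)
        frac = CompartmentFractions.from_array(rng.dirichlet([8, 2, 2], S))
        shifted = two_step_cancer_profile(observed, ref_i + 3.0, ref_s + 3.0,
                                          frac, median_match=True)
        base = two_step_cancer_profile(observed, ref_i, ref_s, frac,
                                       median_match=True)
        # a common shift of the references is undone by median matching
        np.testing.assert_allclose(shifted.values, base.values, atol=1e-9)

    def test_low_cancer_fraction_rejected(self, rng):
        observed = ExpressionMatrix(rng.normal(2, 1, (5, 2)))
        frac = CompartmentFractions.from_array(
            np.array([[0.001, 0.5, 0.499], [0.5, 0.3, 0.2]]))
        with pytest.raises(DeclustError):
            two_step_cancer_profile(observed, np.zeros(5), np.zeros(5), frac)


class TestQuantileNormalize:
    def test_columns_share_sorted_values(self, rng):
        m = ExpressionMatrix(rng.normal(0, 1, (30, 5)))
        qn = quantile_normalize(m)
        ref = np.sort(qn.values[:, 0])
        for j in range(1, 5):
            np.testing.assert_allclose(np.sort(qn.values[:, j]), ref, atol=1e-12)

    def test_preserves_within_column_ranks(self, rng):
        m = ExpressionMatrix(rng.normal(0, 1, (30, 4)))
        qn = quantile_normalize(m)
        for j in range(4):
            assert np.array_equal(np.argsort(m.values[:, j]),
                                  np.argsort(qn.values[:, j]))


class TestBaselineCluster:
    def test_identical_samples_co_clustered(self, rng):
        col = rng.normal(0, 1, 20)
        values = np.column_stack([col, col, col + 5, col + 5, col, col + 5])
        asn = baseline_cluster(ExpressionMatrix(values), 2,
                               config=OptimizerConfig(seed=0, kmeans_restarts=3))
        assert asn.labels[0] == asn.labels[1] == asn.labels[4]
        assert asn.labels[2] == asn.labels[3] == asn.labels[5]
        assert asn.labels[0] != asn.labels[2]

    def test_two_step_recovers_truth_on_exact_data(self, exact_dataset):
        ds = exact_dataset
        cancer = two_step_cancer_profile(ds.observed,
                                         ds.true_profiles.immune_profile,
                                         ds.true_profiles.stromal_profile,
                                         ds.true_fractions, median_match=False)
        asn = baseline_cluster(cancer, 3, "two_step",
                               OptimizerConfig(seed=0, kmeans_restarts=10))
        acc, _, _ = clustering_accuracy(ds.true_assignment.zero_based(),
                                        asn.zero_based())
        assert acc == 1.0

    def test_invalid_mode_rejected(self, rng):
        with pytest.raises(DeclustError):
            baseline_cluster(ExpressionMatrix(rng.normal(0, 1, (5, 4))), 2,
                             "other")


class TestClusteringAccuracy:
    def test_hungarian_matches_exhaustive_permutation_search(self, rng):
        for K in (2, 3, 4, 5):
            t = rng.integers(0, K, 40)
            e = rng.integers(0, K, 40)
            acc, _, _ = clustering_accuracy(t, e)
            brute = max(np.mean(np.array([p[x] for x in e]) == t)
                        for p in itertools.permutations(range(K)))
            assert acc == pytest.approx(brute, abs=1e-12)

    def test_permutation_invariance(self, rng):
        t = rng.integers(0, 3, 30)
        perm = np.array([2, 0, 1])
        acc, _, ari = clustering_accuracy(t, perm[t])
        assert acc == 1.0 and ari == pytest.approx(1.0)

    def test_random_assignment_approaches_one_over_k(self, rng):
        n, K = 20000, 3
        t = rng.integers(0, K, n)
        e = rng.integers(0, K, n)
        acc, _, _ = clustering_accuracy(t, e)
        assert acc == pytest.approx(1 / 3, abs=0.02)


class TestEvaluateRecovery:
    def test_truth_estimate_scores_one(self, exact_dataset):
        report = evaluate_recovery(exact_dataset, _truth_state(exact_dataset))
        assert report.clustering_accuracy == 1.0
        assert report.fraction_accuracy == pytest.approx(1.0, abs=1e-12)
        assert report.profile_accuracy == pytest.approx(1.0, abs=1e-12)

    def test_profile_metric_invariant_to_common_shift(self, exact_dataset):
        ds = exact_dataset
        state = _truth_state(ds)
        state.profiles.cancer_profiles = state.profiles.cancer_profiles + 1.7
        state.profiles.immune_profile = state.profiles.immune_profile + 1.7
        state.profiles.stromal_profile = state.profiles.stromal_profile + 1.7
        report = evaluate_recovery(ds, state)
        assert report.profile_accuracy == pytest.approx(1.0, abs=1e-12)

    def test_bare_assignment_gives_clustering_metrics_only(self, exact_dataset):
        ds = exact_dataset
        report = evaluate_recovery(ds, ds.true_assignment)
        assert report.clustering_accuracy == 1.0
        assert np.isnan(report.fraction_accuracy)

    def test_summary_averages_replicates(self, exact_dataset):
        r = evaluate_recovery(exact_dataset, exact_dataset.true_assignment)
        summary = summarize_reports([r, r, r])
        assert summary["clustering_accuracy"] == 1.0
        assert summary["n_replicates"] == 3


class TestNnlsFractions:
    def test_recovers_fractions_on_exact_data(self, exact_dataset):
        ds = exact_dataset
        ref_cancer = np.median(ds.true_profiles.cancer_profiles, axis=1)
        est = estimate_fractions_nnls(ds.observed, ref_cancer,
                                      ds.true_profiles.immune_profile,
                                      ds.true_profiles.stromal_profile)
        true = ds.true_fractions.as_array()
        corr = np.corrcoef(true[:, 1], est.as_array()[:, 1])[0, 1]
        assert corr > 0.95
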