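import itertools

import numpy as np
import pytest

from declust.core_model import (
    CompartmentFractions,
    CompartmentProfiles,
    DeclustError,
    ExpressionMatrix,
    SubtypeAssignment,
    compute_mse,
    reconstruct_mixture,
)
from declust.optimizer import (
    OptimizerConfig,
    fit_single_subtype,
    init_subtypes,
    optimize_fractions,
    optimize_profiles,
    reassign_subtypes,
    run_declust,
    run_inner_loop,
)


def _exact_instance(rng, G=30, S=15, K=3):
    profiles = CompartmentProfiles(rng.normal(2, 1.2, (G, K)),
                                   rng.normal(2, 1.2, G), rng.normal(2, 1.2, G))
    fractions = CompartmentFractions.from_array(rng.dirichlet([8, 3, 2], S))
    assignment = SubtypeAssignment(rng.integers(1, K + 1, S), K)
    observed = reconstruct_mixture(profiles, fractions, assignment)
    return observed, profiles, fractions, assignment


class TestFitSingleSubtype:
    def test_recovers_truth_on_exact_single_subtype_data(self, rng):
        observed, profiles, fractions, _ = _exact_instance(rng, G=25, S=40, K=1)
        # wide profile box: weak-compartment truths can sit far below the
        # observed mixture range
        est = fit_single_subtype(observed, fractions,
                                 OptimizerConfig(profile_bounds_pad=8.0))
        np.testing.assert_allclose(est.cancer_profiles, profiles.cancer_profiles,
                                   atol=1e-3)
        np.testing.assert_allclose(est.immune_profile, profiles.immune_profile,
                                   atol=1e-3)
        np.testing.assert_allclose(est.stromal_profile, profiles.stromal_profile,
                                   atol=1e-3)

    def test_pure_cancer_cohort_gives_row_means(self, rng):
        G, S = 10, 8
        observed = ExpressionMatrix(rng.normal(2, 1, (G, S)))
        fractions = CompartmentFractions.from_array(
            np.tile([1.0, 0.0, 0.0], (S, 1)))
        est = fit_single_subtype(observed, fractions)
        np.testing.assert_allclose(est.cancer_profiles[:, 0],
                                   observed.values.mean(axis=1), atol=1e-6)

    def test_descent_from_initialization(self, rng):
        observed, _, fractions, assignment = _exact_instance(rng, K=1)
        noisy = ExpressionMatrix(observed.values
                                 + rng.normal(0, 0.4, observed.values.shape))
        init_prof = CompartmentProfiles(
            np.repeat(noisy.values.mean(axis=1)[:, None], 1, axis=1),
            noisy.values.mean(axis=1), noisy.values.mean(axis=1))
        before = compute_mse(noisy, init_prof, fractions, assignment)
        est = fit_single_subtype(noisy, fractions)
        after = compute_mse(noisy, est, fractions, assignment)
        assert after <= before + 1e-9


class TestInitSubtypes:
    def test_k1_gives_all_ones(self):
        asn = init_subtypes(np.zeros((5, 7)), 1)
        assert list(asn.labels) == [1] * 7

    def test_separated_blobs_match_exhaustive_partition(self, rng):
        # 8 samples, 2 well separated residual blobs
        blob = np.array([0, 0, 1, 1, 0, 1, 0, 1])
        residuals = rng.normal(0, 0.05, (6, 8)) + 4.0 * blob
        asn = init_subtypes(residuals, 2, OptimizerConfig(seed=0))
        # oracle: best 2-partition by within-cluster SS over all 2^8 splits
        X = residuals.T
        best, best_ss = None, np.inf
        for bits in itertools.product([0, 1], repeat=8):
            b = np.array(bits)
            if b.min() == b.max():
                continue
            ss = sum(((X[b == g] - X[b == g].mean(axis=0)) ** 2).sum()
                     for g in (0, 1))
            if ss < best_ss:
                best_ss, best = ss, b
        agree = np.mean(asn.zero_based() == best)
        assert agree in (0.0, 1.0)  # identical up to label swap

    def test_labels_renumbered_by_descending_size(self, rng):
        residuals = np.hstack([np.full((4, 6), 5.0), np.zeros((4, 2))])
        residuals += rng.normal(0, 0.01, residuals.shape)
        asn = init_subtypes(residuals, 2, OptimizerConfig(seed=0))
        # majority cluster must carry label 1
        assert np.sum(asn.labels == 1) == 6

    def test_permutation_equivariance_on_separated_data(self, rng):
        blob = np.array([0, 0, 0, 1, 1, 1])
        residuals = rng.normal(0, 0.05, (5, 6)) + 6.0 * blob
        perm = np.array([3, 0, 4, 1, 5, 2])
        a1 = init_subtypes(residuals, 2, OptimizerConfig(seed=0)).labels
        a2 = init_subtypes(residuals[:, perm], 2, OptimizerConfig(seed=0)).labels
        assert np.array_equal(a1[perm], a2) or np.array_equal(3 - a1[perm], a2)

    def test_more_subtypes_than_samples_raises(self):
        with pytest.raises(DeclustError):
            init_subtypes(np.zeros((3, 2)), 3)


class TestOptimizeProfiles:
    def test_recovers_truth_with_true_fractions_and_labels(self, rng):
        observed, profiles, fractions, assignment = _exact_instance(rng, S=30)
        warm = CompartmentProfiles(
            np.repeat(observed.values.mean(axis=1)[:, None], 3, axis=1),
            observed.values.mean(axis=1), observed.values.mean(axis=1))
        est = optimize_profiles(observed, fractions, assignment, warm,
                                OptimizerConfig(profile_bounds_pad=8.0))
        np.testing.assert_allclose(est.cancer_profiles, profiles.cancer_profiles,
                                   atol=1e-3)
        np.testing.assert_allclose(est.immune_profile, profiles.immune_profile,
                                   atol=1e-3)

    def test_empty_subtype_keeps_warm_start(self, rng):
        observed, profiles, fractions, _ = _exact_instance(rng, K=3)
        # no sample assigned to subtype 3
        labels = np.where(np.arange(observed.n_samples) % 2 == 0, 1, 2)
        assignment = SubtypeAssignment(labels, 3)
        est = optimize_profiles(observed, fractions, assignment, profiles)
        np.testing.assert_allclose(est.cancer_profiles[:, 2],
                                   profiles.cancer_profiles[:, 2], atol=1e-12)

    def test_objective_never_worse_than_warm_start(self, rng):
        observed, profiles, fractions, assignment = _exact_instance(rng)
        noisy = ExpressionMatrix(observed.values
                                 + rng.normal(0, 0.5, observed.values.shape))
        before = compute_mse(noisy, profiles, fractions, assignment)
        est = optimize_profiles(noisy, fractions, assignment, profiles)
        after = compute_mse(noisy, est, fractions, assignment)
        assert after <= before + 1e-9


class TestReassignSubtypes:
    def test_matches_per_sample_brute_force(self, rng):
        for K, S in [(2, 12), (3, 20), (5, 20)]:
            observed, profiles, fractions, _ = _exact_instance(rng, G=15, S=S, K=K)
            noisy = ExpressionMatrix(observed.values
                                     + rng.normal(0, 0.6, observed.values.shape))
            est = reassign_subtypes(noisy, profiles, fractions)
            for j in range(S):
                errs = []
                for k in range(1, K + 1):
                    asn = SubtypeAssignment(np.full(S, k), K)
                    r = noisy.values - reconstruct_mixture(profiles, fractions,
                                                           asn).values
                    errs.append(np.sum(r[:, j] ** 2))
                assert est.labels[j] == int(np.argmin(errs)) + 1

    def test_sample_matching_one_subtype_exactly(self, rng):
        observed, profiles, fractions, _ = _exact_instance(rng, K=3)
        forced = SubtypeAssignment(np.full(observed.n_samples, 2), 3)
        exact = reconstruct_mixture(profiles, fractions, forced)
        est = reassign_subtypes(exact, profiles, fractions)
        assert np.all(est.labels == 2)

    def test_ties_break_to_lowest_index(self):
        profiles = CompartmentProfiles(np.array([[1.0, 2.0, 1.0]]),
                                       np.array([1.0]), np.array([1.0]))
        fractions = CompartmentFractions.from_array(np.array([[1.0, 0.0, 0.0]]))
        observed = ExpressionMatrix(np.array([[1.0]]))
        est = reassign_subtypes(observed, profiles, fractions)
        assert est.labels[0] == 1  # subtypes 1 and 3 tie exactly

    def test_label_permutation_equivariance(self, rng):
        observed, profiles, fractions, _ = _exact_instance(rng, K=3)
        noisy = ExpressionMatrix(observed.values
                                 + rng.normal(0, 0.4, observed.values.shape))
        base = reassign_subtypes(noisy, profiles, fractions).zero_based()
        perm = np.array([2, 0, 1])
        permuted = CompartmentProfiles(profiles.cancer_profiles[:, perm],
                                       profiles.immune_profile,
                                       profiles.stromal_profile)
        out = reassign_subtypes(noisy, permuted, fractions).zero_based()
        inv = np.argsort(perm)
        assert np.array_equal(inv[base], out)


class TestOptimizeFractions:
    def test_recovers_known_fractions_zero_noise(self, rng):
        observed, profiles, fractions, assignment = _exact_instance(rng, G=60,
                                                                    S=10)
        warm = CompartmentFractions.from_array(
            np.tile([1 / 3, 1 / 3, 1 / 3], (10, 1)))
        est = optimize_fractions(observed, profiles, assignment, warm)
        np.testing.assert_allclose(est.as_array(), fractions.as_array(),
                                   atol=1e-3)

    def test_pure_immune_sample_pushes_f_immune_to_one(self, rng):
        G = 40
        profiles = CompartmentProfiles(rng.normal(2, 1, (G, 1)),
                                       rng.normal(2, 1, G), rng.normal(2, 1, G))
        observed = ExpressionMatrix(profiles.immune_profile[:, None])
        warm = CompartmentFractions.from_array(np.array([[0.4, 0.3, 0.3]]))
        est = optimize_fractions(observed, profiles,
                                 SubtypeAssignment([1], 1), warm)
        assert est.f_immune[0] > 0.99

    def test_output_on_simplex_and_descent(self, rng):
        observed, profiles, fractions, assignment = _exact_instance(rng)
        noisy = ExpressionMatrix(observed.values
                                 + rng.normal(0, 0.5, observed.values.shape))
        warm = CompartmentFractions.from_array(
            np.tile([0.5, 0.25, 0.25], (observed.n_samples, 1)))
        est = optimize_fractions(noisy, profiles, assignment, warm)
        arr = est.as_array()
        assert np.all(arr >= -1e-12) and np.all(arr <= 1 + 1e-12)
        np.testing.assert_allclose(arr.sum(axis=1), 1.0, atol=1e-8)
        before = compute_mse(noisy, profiles, warm, assignment)
        after = compute_mse(noisy, profiles, est, assignment)
        assert after <= before + 1e-9


class TestInnerLoop:
    def test_k1_reduces_to_single_profile_fit(self, rng):
        observed, _, fractions, _ = _exact_instance(rng, K=1)
        state = run_inner_loop(observed, fractions, 1)
        assert np.all(state.assignment.labels == 1)

    def test_objective_history_non_increasing(self, rng):
        observed, _, fractions, _ = _exact_instance(rng, G=40, S=24, K=3)
        noisy = ExpressionMatrix(observed.values
                                 + rng.normal(0, 0.3, observed.values.shape))
        state = run_inner_loop(noisy, fractions, 3, OptimizerConfig(seed=0))
        diffs = np.diff(state.history)
        assert np.all(diffs <= 1e-9)

    def test_recovers_assignment_on_exact_data(self, rng):
        observed, _, fractions, assignment = _exact_instance(rng, G=60, S=30,
                                                             K=3)
        state = run_inner_loop(observed, fractions, 3, OptimizerConfig(seed=0))
        from declust.baselines import clustering_accuracy
        acc, _, _ = clustering_accuracy(assignment.zero_based(),
                                        state.assignment.zero_based())
        assert acc == 1.0


class TestRunDeclust:
    def test_determinism_same_seed_bitwise(self, exact_dataset, fast_config):
        ds = exact_dataset
        s1 = run_declust(ds.observed, ds.markers, 3, fast_config)
        s2 = run_declust(ds.observed, ds.markers, 3, fast_config)
        assert s1.objective == s2.objective
        np.testing.assert_array_equal(s1.assignment.labels, s2.assignment.labels)
        np.testing.assert_array_equal(s1.profiles.cancer_profiles,
                                      s2.profiles.cancer_profiles)
        np.testing.assert_array_equal(s1.fractions.as_array(),
                                      s2.fractions.as_array())

    def test_outer_history_non_increasing_and_metadata(self, noisy_dataset,
                                                       fast_config):
        ds = noisy_dataset
        state = run_declust(ds.observed, ds.markers, 3, fast_config)
        diffs = np.diff(state.history)
        assert np.all(diffs <= 1e-9)
        assert state.metadata["seed"] == fast_config.seed
        assert state.metadata["constants"]["c_immune"] > 0
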