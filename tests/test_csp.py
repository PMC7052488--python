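"""CSP eigenstructure, atom features, bags, and the Rayleigh relevance map."""

import numpy as np
import pytest
from scipy.stats import ortho_group

from milatoms import (EEGTrialSet, apply_filter_bank, build_bags,
                      design_filter_bank, estimate_class_covariances,
                      extract_atom, fit_csp, group_concat, plan_windows,
                      rayleigh_map, segment_trials)
from milatoms.csp import ClassCovariances, atoms_from_covariances
from milatoms.exceptions import DataError, NumericalError, ParameterError


def _random_spd(rng, dim=4, lo=0.5, hi=2.0):
    Q = ortho_group.rvs(dim, random_state=rng)
    return Q @ np.diag(rng.uniform(lo, hi, dim)) @ Q.T


class TestClassCovariances:
    def test_identical_trials_give_equal_class_covariances(self, rng):
        X = rng.standard_normal((1, 1, 1, 4, 100))
        windowed = np.repeat(X, 6, axis=0)
        labels = np.array([1, 1, 1, -1, -1, -1])
        cc = estimate_class_covariances(windowed, labels, 0, 0,
                                        trace_normalize=False)
        np.testing.assert_allclose(cc.sigma_pos, cc.sigma_neg, atol=1e-12)
        Xc = X[0, 0, 0] - X[0, 0, 0].mean(axis=-1, keepdims=True)
        np.testing.assert_allclose(cc.sigma_pos, Xc @ Xc.T / 100, atol=1e-12)

    def test_white_noise_covariance_near_identity(self, rng):
        windowed = rng.standard_normal((300, 1, 1, 5, 200))
        labels = np.where(np.arange(300) < 150, 1, -1)
        cc = estimate_class_covariances(windowed, labels, 0, 0,
                                        trace_normalize=False)
        for s in (cc.sigma_pos, cc.sigma_neg):
            off = np.abs(s - np.diag(np.diag(s))).max()
            assert off < 0.1 * np.diag(s).min()

    def test_covariance_difference_aligns_with_planted_pattern(self, small_dataset):
        cfg, trials, truth = small_dataset
        bank = design_filter_bank(8, 16, 4, 4)  # bands (8,12), (12,16)
        filtered = apply_filter_bank(trials, bank)
        scheme = plan_windows(trials.n_samples, 0.5, trials.fs)
        windowed = segment_trials(filtered, scheme)
        widx = np.argmin(np.abs(scheme.centers_s - 1.0))  # inside the ERD
        cc = estimate_class_covariances(windowed, trials.labels, 0, widx)
        diff = cc.sigma_pos - cc.sigma_neg
        w, V = np.linalg.eigh(diff)
        top = V[:, np.argmax(np.abs(w))]
        corr = abs(top @ truth.mixing_matrix[:, truth.discriminative_source_index])
        assert corr >= 0.9

    def test_single_class_rejected(self, rng):
        windowed = rng.standard_normal((4, 1, 1, 3, 50))
        with pytest.raises(DataError):
            estimate_class_covariances(windowed, np.ones(4), 0, 0)


class TestFitCsp:
    def test_identical_classes_all_eigenvalues_one(self):
        cc = ClassCovariances(np.eye(3), np.eye(3))
        model = fit_csp(cc, M=1, shrinkage=0.0)
        np.testing.assert_allclose(model.eigenvalues, 1.0, atol=1e-12)

    def test_diagonal_analytic_case(self):
        cc = ClassCovariances(np.diag([4.0, 1.0]), np.eye(2))
        model = fit_csp(cc, M=1, shrinkage=0.0)
        assert model.eigenvalues[0] == pytest.approx(4.0)
        np.testing.assert_allclose(np.abs(model.W[0]), [1.0, 0.0], atol=1e-12)

    def test_top_eigenvalue_matches_random_search(self, rng):
        """Brute-force Rayleigh-quotient maximization over 1e5 unit vectors."""
        for _ in range(5):
            sp, sn = _random_spd(rng), _random_spd(rng)
            model = fit_csp(ClassCovariances(sp, sn), M=2, shrinkage=0.0)
            W = rng.standard_normal((100_000, 4))
            W /= np.linalg.norm(W, axis=1, keepdims=True)
            J = (np.einsum("ij,jk,ik->i", W, sp, W)
                 / np.einsum("ij,jk,ik->i", W, sn, W))
            assert model.eigenvalues[0] >= J.max() - 1e-12
            assert (model.eigenvalues[0] - J.max()) / model.eigenvalues[0] < 0.01

    def test_label_swap_inverts_and_reverses_eigenvalues(self, rng):
        sp, sn = _random_spd(rng, 6), _random_spd(rng, 6)
        a = fit_csp(ClassCovariances(sp, sn), M=2, shrinkage=0.0)
        b = fit_csp(ClassCovariances(sn, sp), M=2, shrinkage=0.0)
        np.testing.assert_allclose(a.eigenvalues, 1.0 / b.eigenvalues[::-1],
                                   atol=1e-8)

    def test_row_normalization_does_not_change_eigenvalues(self, rng):
        sp, sn = _random_spd(rng, 5), _random_spd(rng, 5)
        model = fit_csp(ClassCovariances(sp, sn), M=2, shrinkage=0.0)
        np.testing.assert_allclose(np.linalg.norm(model.W, axis=1), 1.0,
                                   atol=1e-12)
        for lam, w in zip(model.eigenvalues, model.W):
            assert (w @ sp @ w) / (w @ sn @ w) == pytest.approx(lam)

    def test_singular_denominator_without_shrinkage_raises(self):
        sn = np.diag([1.0, 0.0])
        with pytest.raises(NumericalError, match="shrinkage"):
            fit_csp(ClassCovariances(np.eye(2), sn), M=1, shrinkage=0.0)
        fit_csp(ClassCovariances(np.eye(2), sn), M=1, shrinkage=0.1)

    def test_too_many_pairs_rejected(self):
        with pytest.raises(ParameterError):
            fit_csp(ClassCovariances(np.eye(4), np.eye(4)), M=3)


class TestAtoms:
    def test_single_band_direct_formula(self):
        rng = np.random.default_rng(1)
        T = 100_000
        Z = np.stack([2.0 * rng.standard_normal(T), rng.standard_normal(T)])
        d = extract_atom(Z[None])
        np.testing.assert_allclose(d, [np.log(4 / 5), np.log(1 / 5)], atol=0.02)

    def test_default_dimensions(self, rng):
        Z = rng.standard_normal((17, 6, 50))
        assert extract_atom(Z).shape == (102,)

    def test_band_blocks_are_normalized_log_distributions(self, rng):
        Z = rng.standard_normal((5, 4, 60))
        d = extract_atom(Z).reshape(5, 4)
        np.testing.assert_allclose(np.exp(d).sum(axis=1), 1.0, atol=1e-10)

    def test_atoms_invariant_to_global_scaling(self, rng):
        Z = rng.standard_normal((3, 4, 80))
        np.testing.assert_allclose(extract_atom(Z), extract_atom(7.3 * Z),
                                   atol=1e-10)

    def test_degenerate_window_rejected(self):
        with pytest.raises(DataError):
            extract_atom(np.zeros((2, 2, 10)))

    def test_atoms_from_covariances_matches_direct_path(self, rng):
        """Quadratic-form atoms equal atoms from explicit projections."""
        X = rng.standard_normal((4, 2, 1, 5, 64))  # trials,bands,windows,C,T
        Xc = X - X.mean(axis=-1, keepdims=True)
        covs = np.einsum("rfwct,rfwdt->rfwcd", Xc, Xc) / 64
        W = rng.standard_normal((2, 1, 4, 5))
        via_cov = atoms_from_covariances(W, covs)
        for r in range(4):
            Z = np.einsum("fwmc,fwct->fwmt", W, X[r])[:, 0]
            np.testing.assert_allclose(via_cov[r, 0], extract_atom(Z),
                                       atol=1e-10)


class TestBags:
    @pytest.mark.parametrize("tau,expected", [(2.0, 1), (0.2, 91)])
    def test_bag_sizes_match_window_counts(self, rng, tau, expected):
        scheme = plan_windows(500, tau, 250.0)
        atoms = rng.standard_normal((3, scheme.n_windows, 12))
        bags = build_bags(atoms, np.array([1, -1, 1]), tau)
        assert all(b.n_instances == expected for b in bags)

    def test_total_instances_across_all_window_lengths(self):
        total = sum(plan_windows(500, round(0.2 + 0.1 * i, 1), 250.0).n_windows
                    for i in range(19))
        assert total == 337

    def test_bag_labels_follow_trials(self, rng):
        bags = build_bags(rng.standard_normal((2, 3, 4)),
                          np.array([1, -1]), 0.5)
        assert [b.label for b in bags] == [1, -1]


class TestRayleighMap:
    def test_null_data_gives_J_near_one(self, rng):
        data = rng.standard_normal((60, 4, 500))
        labels = np.where(np.arange(60) < 30, 1, -1)
        trials = EEGTrialSet(data, labels, 250.0)
        bank = design_filter_bank(8, 16, 4, 4)
        rm = rayleigh_map(trials, bank, tau=2.0, M=2)
        assert np.all(rm.J_values > 0)
        assert np.all(rm.J_values < 1.6)  # small-sample bias only

    def test_spectral_relevance_peaks_in_planted_band(self, small_dataset):
        cfg, trials, truth = small_dataset
        bank = design_filter_bank(4, 24, 4, 4)
        rm = rayleigh_map(trials, bank, tau=1.0, M=3)
        lo, hi = bank.bands[int(np.argmax(rm.spectral_relevance))]
        assert lo < truth.erd_band[1] and hi > truth.erd_band[0]

    def test_map_invariant_to_channel_permutation(self, small_dataset, rng):
        _, trials, _ = small_dataset
        sub = EEGTrialSet(trials.data[:20], trials.labels[:20], trials.fs)
        perm = rng.permutation(sub.n_channels)
        permuted = EEGTrialSet(sub.data[:, perm], sub.labels, sub.fs)
        bank = design_filter_bank(8, 12, 4, 2)
        a = rayleigh_map(sub, bank, tau=1.0, M=2, shrinkage=0.0)
        b = rayleigh_map(permuted, bank, tau=1.0, M=2, shrinkage=0.0)
        np.testing.assert_allclose(a.J_values, b.J_values, atol=1e-8)


class TestGroupConcat:
    def test_stacks_trials_and_labels(self, small_dataset):
        _, trials, _ = small_dataset
        merged = group_concat([trials, trials])
        assert merged.n_trials == 2 * trials.n_trials
        np.testing.assert_array_equal(merged.labels[:trials.n_trials],
                                      trials.labels)

    def test_single_set_identity(self, small_dataset):
        _, trials, _ = small_dataset
        merged = group_concat([trials])
        np.testing.assert_array_equal(merged.data, trials.data)

    def test_mismatched_shapes_rejected(self, small_dataset):
        _, trials, _ = small_dataset
        other = EEGTrialSet(trials.data[:, :-1], trials.labels, trials.fs)
        with pytest.raises(DataError):
            group_concat([trials, other])
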