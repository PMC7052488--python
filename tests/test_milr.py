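"""Noisy-OR multiple-instance logistic regression: oracle equivalence,
EM monotonicity, responsibilities, prediction, and atom refinement."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from milatoms import (bag_predict, build_bags, gamma_weights, milr_fit,
                      refine_atoms)
from milatoms.csp import AtomBag
from milatoms.milr import MILRModel
from milatoms.exceptions import DataError, ParameterError


def _single_instance_bags(rng, n=200, p=8):
    X = rng.standard_normal((n, p))
    w = np.r_[1.5, -2.0, np.zeros(p - 2)]
    prob = 1.0 / (1.0 + np.exp(-(X @ w + 0.3)))
    y = np.where(rng.random(n) < prob, 1, -1)
    bags = [AtomBag(i, X[i:i + 1], 0.5, int(y[i])) for i in range(n)]
    return X, y, bags


class TestFit:
    @pytest.mark.parametrize("alpha", [0.5, 2.0, 10.0])
    def test_single_instance_bags_match_penalized_logistic(self, rng, alpha):
        """With one instance per bag the model is ordinary L1 logistic
        regression; coefficients must agree with an independent solver."""
        X, y, bags = _single_instance_bags(rng)
        model = milr_fit(bags, alpha=alpha, tol=1e-10, max_sweeps=20_000)
        oracle = LogisticRegression(solver="saga", l1_ratio=1.0,
                                    C=1.0 / alpha, tol=1e-10,
                                    max_iter=200_000)
        oracle.fit(X, (y == 1).astype(int))
        assert np.abs(model.beta - oracle.coef_[0]).max() <= 1e-4
        assert abs(model.beta0 - oracle.intercept_[0]) <= 1e-4

    def test_huge_alpha_zeroes_weights_with_symmetric_null(self, rng):
        X = rng.standard_normal((40, 5))
        y = np.r_[np.ones(20, int), -np.ones(20, int)]
        bags = [AtomBag(i, X[i:i + 1], 0.5, int(y[i])) for i in range(40)]
        model = milr_fit(bags, alpha=1e6, tol=1e-12)
        assert np.count_nonzero(model.beta) == 0
        assert abs(model.beta0) <= 1e-6

    def test_separable_toy_recovers_sign(self):
        pos = [AtomBag(i, np.array([[1.0], [-1.0]]), 0.5, 1) for i in range(6)]
        neg = [AtomBag(i + 6, np.array([[-1.0], [-1.0]]), 0.5, -1)
               for i in range(6)]
        model = milr_fit(pos + neg, alpha=0.5)
        assert model.beta[0] > 0

    def test_objective_trace_non_increasing(self, rng):
        X = rng.standard_normal((30, 4, 6))  # 30 bags x 4 instances
        y = np.where(np.arange(30) < 15, 1, -1)
        bags = build_bags(X, y, 0.5)
        model = milr_fit(bags, alpha=1.0, tol=1e-9, max_sweeps=500)
        tr = model.objective_trace
        assert np.all(np.diff(tr) <= 1e-9 * np.maximum(1.0, np.abs(tr[:-1])))

    def test_sparsity_grows_with_alpha(self, rng):
        _, _, bags = _single_instance_bags(rng, n=120)
        n0 = np.count_nonzero(milr_fit(bags, alpha=1.0).beta)
        n1 = np.count_nonzero(milr_fit(bags, alpha=10.0).beta)
        assert n1 <= n0

    def test_prediction_invariant_to_instance_order(self, rng):
        X = rng.standard_normal((5, 6))
        bag = AtomBag(0, X, 0.5, 1)
        shuffled = AtomBag(0, X[::-1].copy(), 0.5, 1)
        model = MILRModel(0.2, rng.standard_normal(6), 0.0, True,
                          np.zeros(1), 0)
        assert bag_predict(model, bag)[0] == bag_predict(model, shuffled)[0]

    def test_bad_inputs_rejected(self, rng):
        X = rng.standard_normal((4, 1, 3))
        only_pos = build_bags(X, np.ones(4, dtype=int), 0.5)
        with pytest.raises(DataError):
            milr_fit(only_pos, alpha=1.0)
        with pytest.raises(DataError):
            milr_fit([], alpha=1.0)


class TestGammaWeights:
    def test_single_instance_gamma_is_one(self):
        model = MILRModel(0.3, np.array([1.0]), 0.0, True, np.zeros(1), 0)
        bag = AtomBag(0, np.array([[0.7]]), 0.5, 1)
        assert gamma_weights(model, bag)[0] == pytest.approx(1.0)

    def test_two_instances_at_half(self):
        model = MILRModel(0.0, np.zeros(3), 0.0, True, np.zeros(1), 0)
        bag = AtomBag(0, np.zeros((2, 3)), 0.5, 1)
        np.testing.assert_allclose(gamma_weights(model, bag), 2.0 / 3.0)

    def test_gamma_monotone_in_own_score_and_bounded(self):
        model = MILRModel(0.0, np.array([1.0]), 0.0, True, np.zeros(1), 0)
        others = np.array([[-0.5], [0.2]])
        gammas = []
        for x in np.linspace(-3, 3, 13):
            bag = AtomBag(0, np.vstack([[x], others]), 0.5, 1)
            g = gamma_weights(model, bag)
            h = 1.0 / (1.0 + np.exp(-bag.instances[:, 0]))
            assert np.all(g >= h - 1e-12) and np.all(g <= 1.0)
            gammas.append(g[0])
        assert np.all(np.diff(gammas) > 0)


class TestBagPredict:
    def test_null_model_single_instance(self):
        model = MILRModel(0.0, np.zeros(2), 0.0, True, np.zeros(1), 0)
        prob, label = bag_predict(model, AtomBag(0, np.zeros((1, 2)), 0.5, 1))
        assert prob == pytest.approx(0.5)
        assert label == -1  # 0.5 is not > 0.5

    def test_noisy_or_of_two_halves(self):
        model = MILRModel(0.0, np.zeros(2), 0.0, True, np.zeros(1), 0)
        prob, label = bag_predict(model, AtomBag(0, np.zeros((2, 2)), 0.5, 1))
        assert prob == pytest.approx(0.75)
        assert label == 1

    def test_adding_instance_never_decreases_probability(self, rng):
        model = MILRModel(-0.3, rng.standard_normal(4), 0.0, True,
                          np.zeros(1), 0)
        X = rng.standard_normal((6, 4))
        probs = [bag_predict(model, AtomBag(0, X[:k], 0.5, 1))[0]
                 for k in range(1, 7)]
        assert np.all(np.diff(probs) >= -1e-15)


class TestRefineAtoms:
    def _bags(self, rng, n=8, p=5):
        return build_bags(rng.standard_normal((n, 3, p)),
                          np.where(np.arange(n) < n // 2, 1, -1), 0.5)

    def test_keeps_exact_support(self, rng):
        bags = self._bags(rng)
        beta = np.array([0.0, 1.2, 0.0, -0.4, 0.002])
        model = MILRModel(0.0, beta, 1.0, True, np.zeros(1), 0)
        refined, mask = refine_atoms(bags, model, threshold=0.0)
        np.testing.assert_array_equal(mask.kept_coordinates, [1, 3, 4])
        assert refined[0].instances.shape == (3, 3)
        np.testing.assert_array_equal(refined[2].instances,
                                      bags[2].instances[:, [1, 3, 4]])

    def test_threshold_above_max_beta_is_error(self, rng):
        bags = self._bags(rng)
        model = MILRModel(0.0, np.array([0.1, 0.2, 0, 0, 0]), 1.0, True,
                          np.zeros(1), 0)
        with pytest.raises(ParameterError):
            refine_atoms(bags, model, threshold=0.5)

    def test_kept_coordinates_enriched_in_erd_bands(self, small_dataset):
        """On synthetic ERD data the refined support concentrates in the
        filter-bank bands overlapping the planted rhythm."""
        from milatoms import (apply_filter_bank, design_filter_bank,
                              plan_windows)
        from milatoms.csp import (AtomBag, _class_covs_from_trial_covs,
                                  atoms_from_covariances, fit_csp,
                                  window_covariances)
        from milatoms.milr import milr_fit

        cfg, trials, truth = small_dataset
        bank = design_filter_bank(4, 20, 4, 4)
        filtered = apply_filter_bank(trials, bank)
        scheme = plan_windows(trials.n_samples, 1.0, trials.fs)
        covs = window_covariances(filtered, scheme)
        M = 3
        W = np.empty((bank.n_bands, scheme.n_windows, 2 * M,
                      trials.n_channels))
        for f in range(bank.n_bands):
            for t in range(scheme.n_windows):
                cc = _class_covs_from_trial_covs(covs[:, f, t], trials.labels)
                W[f, t] = fit_csp(cc, M=M).W_retained
        atoms = atoms_from_covariances(W, covs)
        bags = [AtomBag(r, atoms[r], 1.0, int(trials.labels[r]))
                for r in range(trials.n_trials)]
        # an alpha in the genuinely sparse regime, where refinement operates
        n_inst = sum(b.n_instances for b in bags)
        model = milr_fit(bags, alpha=1e-2 * n_inst, tol=1e-6, max_sweeps=300)
        kept = np.flatnonzero(model.beta != 0)
        assert kept.size > 0
        band_of = kept // (2 * M)
        erd_bands = [i for i, (lo, hi) in enumerate(bank.bands)
                     if lo < truth.erd_band[1] and hi > truth.erd_band[0]]
        frac_kept = np.isin(band_of, erd_bands).mean()
        frac_uniform = len(erd_bands) / bank.n_bands
        assert frac_kept > frac_uniform
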