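"""One-class loss terms, barycenter fusion and argmax prediction."""

import numpy as np
import pytest
from scipy.optimize import minimize

from microbeat.autodiff import Tensor
from microbeat.ensemble import (
    EnsembleHyper,
    EnsembleModel,
    MiniClassifier,
    anchor_term,
    hreg_term,
    init_from_previous,
    nll_term,
    one_class_loss,
    predict,
    remove_shared,
    score,
    shared_knowledge,
)
from microbeat.features import ExtractorConfig, init_extractor


def _zero_clf(m=4, h1=3, h2=2):
    clf = MiniClassifier(0, m, h1, h2)
    clf.set_theta(np.zeros_like(clf.theta))
    return clf


def _linear_clf(w):
    """Scorer reduced to f(X) = w . X via identity activations."""
    clf = MiniClassifier(0, len(w), 1, 1, activation="identity")
    clf.W1.data = np.asarray(w, float).reshape(-1, 1)
    clf.W2.data = np.array([[1.0]])
    clf.W3.data = np.array([[1.0]])
    return clf


def _tiny_ensemble(thetas, phi=None, tau=0.1):
    cfg = ExtractorConfig(omega=5, hidden1=2, hidden2=2, m=2, seed=0,
                          cell_type="GRU")
    hyper = EnsembleHyper(tau=tau, h1=2, h2=2)
    clfs = []
    for i, th in enumerate(thetas):
        c = MiniClassifier(i, 2, 2, 2)
        c.set_theta(th)
        clfs.append(c)
    return EnsembleModel(cfg, init_extractor(cfg), clfs, hyper,
                         tuple("NSV"[: len(clfs)]), phi)


class TestScore:
    def test_zero_weights_score_zero(self, rng):
        assert score(_zero_clf(), rng.normal(size=4)) == 0.0

    def test_one_dim_toy_odd_function(self):
        clf = MiniClassifier(0, 1, 1, 1)
        clf.set_theta(np.array([1.0, 1.0, 1.0]))
        assert score(clf, np.array([0.0])) == 0.0

    def test_matches_hand_rolled_matmul(self, rng):
        clf = MiniClassifier(0, 6, 5, 4, rng=rng)
        x = rng.normal(size=6)
        by_hand = np.tanh(np.tanh(x @ clf.W1.data) @ clf.W2.data) @ clf.W3.data
        assert abs(score(clf, x) - by_hand[0]) < 1e-10


class TestNll:
    def test_zero_scorer_gives_log_two(self, rng):
        val = float(nll_term(_zero_clf(), rng.normal(size=(3, 4))).data)
        assert abs(val - 0.6931) < 1e-4

    def test_vanishes_for_large_scores(self):
        clf = _linear_clf([30.0])
        val = float(nll_term(clf, np.array([[1.0]])).data)
        assert val < 1e-12

    def test_mean_over_batch(self, rng):
        clf = _zero_clf()
        one = float(nll_term(clf, rng.normal(size=(1, 4))).data)
        two = float(nll_term(clf, rng.normal(size=(2, 4))).data)
        assert abs(one - two) < 1e-12  # score is 0 everywhere

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            nll_term(_zero_clf(), np.empty((0, 4)))


class TestHreg:
    def test_linear_scorer_analytic_value(self, rng):
        clf = _linear_clf([3.0, 4.0])
        for _ in range(3):
            val = float(hreg_term(clf, rng.normal(size=(4, 2)), c=2.0).data)
            assert abs(val - 25.0) < 1e-10

    def test_zero_weights_give_zero(self, rng):
        assert float(hreg_term(_zero_clf(), rng.normal(size=(2, 4))).data) == 0.0

    def test_homogeneous_in_output_weight(self, rng):
        clf = _linear_clf([3.0, 4.0])
        X = rng.normal(size=(4, 2))
        base = float(hreg_term(clf, X, c=2.0).data)
        clf.W3.data *= 2.0
        assert abs(float(hreg_term(clf, X, c=2.0).data) - 4 * base) < 1e-10

    def test_invalid_exponent_rejected(self, rng):
        with pytest.raises(ValueError):
            hreg_term(_zero_clf(), rng.normal(size=(2, 4)), c=0.0)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_finite_difference_input_gradient(self, trial):
        rng = np.random.default_rng(100 + trial)
        clf = MiniClassifier(0, 5, 4, 3, rng=rng)
        x = rng.normal(size=5)
        g = clf.input_gradient(Tensor(x.reshape(1, -1))).data[0]
        eps = 1e-6
        for j in range(5):
            xp, xm = x.copy(), x.copy()
            xp[j] += eps
            xm[j] -= eps
            fd = (score(clf, xp) - score(clf, xm)) / (2 * eps)
            assert abs(g[j] - fd) / max(abs(fd), 1e-8) < 1e-4

    def test_weight_gradient_of_penalty_matches_finite_differences(self, rng):
        # the closed-form input gradient is part of the loss graph, so
        # backprop must give d(hreg)/d(theta) correctly
        clf = MiniClassifier(0, 4, 3, 2, rng=rng)
        X = rng.normal(size=(3, 4))
        loss = hreg_term(clf, X, c=2.0)
        loss.backward()
        g = clf.W1.grad.copy()
        eps = 1e-6
        for idx in [(0, 0), (2, 1), (3, 2)]:
            orig = clf.W1.data[idx]
            clf.W1.data[idx] = orig + eps
            up = float(hreg_term(clf, X, c=2.0).data)
            clf.W1.data[idx] = orig - eps
            dn = float(hreg_term(clf, X, c=2.0).data)
            clf.W1.data[idx] = orig
            fd = (up - dn) / (2 * eps)
            assert abs(g[idx] - fd) / max(abs(fd), 1e-6) < 1e-4


class TestAnchor:
    def test_zero_distance(self):
        clf = _zero_clf()
        assert float(anchor_term(clf, clf.theta).data) == 0.0

    def test_one_two_two(self):
        clf = _zero_clf()
        mu = np.zeros_like(clf.theta)
        th = mu.copy()
        th[:3] = [1.0, 2.0, 2.0]
        clf.set_theta(th)
        assert abs(float(anchor_term(clf, mu).data) - 9.0) < 1e-12

    def test_matches_elementwise_loop(self, rng):
        clf = MiniClassifier(0, 3, 2, 2, rng=rng)
        mu = rng.normal(size=clf.theta.size)
        expect = sum((a - b) ** 2 for a, b in zip(clf.theta, mu))
        assert abs(float(anchor_term(clf, mu).data) - expect) < 1e-10

    def test_absent_anchor_is_zero(self):
        assert float(anchor_term(_zero_clf(), None).data) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            anchor_term(_zero_clf(), np.zeros(3))


class TestOneClassLoss:
    def test_reduces_to_nll_when_eta_pi_zero(self, rng):
        clf = MiniClassifier(0, 4, 3, 2, rng=rng)
        X = rng.normal(size=(5, 4))
        hyper = EnsembleHyper(eta=0.0, pi=0.0)
        assert abs(
            float(one_class_loss(clf, X, hyper).data)
            - float(nll_term(clf, X).data)
        ) < 1e-12

    def test_zero_scorer_first_class(self, rng):
        hyper = EnsembleHyper(eta=1.0, c=2.0, pi=0.1)
        val = float(one_class_loss(_zero_clf(), rng.normal(size=(4, 4)),
                                   hyper, mu_prev=None).data)
        assert abs(val - 0.6931) < 1e-4

    def test_equals_sum_of_terms(self, rng):
        clf = MiniClassifier(0, 4, 3, 2, rng=rng)
        X = rng.normal(size=(5, 4))
        mu = rng.normal(size=clf.theta.size)
        hyper = EnsembleHyper(eta=0.7, c=2.0, pi=0.3)
        total = float(one_class_loss(clf, X, hyper, mu).data)
        parts = (
            float(nll_term(clf, X).data)
            + 0.7 * float(hreg_term(clf, X, 2.0).data)
            + 0.3 * float(anchor_term(clf, mu).data)
        )
        assert abs(total - parts) < 1e-10


class TestSequentialInit:
    def test_second_scorer_centered_on_first(self, rng):
        th1 = rng.normal(size=10)
        init, mu = init_from_previous([th1], rng)
        assert np.array_equal(mu, th1)
        assert np.all(np.abs(init - th1) < 0.1)  # small perturbation

    def test_antisymmetric_pair_centers_at_zero(self, rng):
        th = rng.normal(size=8)
        _, mu = init_from_previous([th, -th], rng)
        assert np.allclose(mu, 0.0)

    def test_mean_of_three_by_direct_averaging(self, rng):
        ths = [rng.normal(size=6) for _ in range(3)]
        _, mu = init_from_previous(ths, rng)
        assert np.allclose(mu, np.mean(ths, axis=0))


class TestSharedKnowledge:
    def test_single_classifier_returns_its_theta(self, rng):
        th = np.random.default_rng(0).normal(size=10)
        model = _tiny_ensemble([th], phi=[1.0])
        assert np.allclose(shared_knowledge(model), th)

    def test_antisymmetric_pair_is_zero(self):
        th = np.random.default_rng(1).normal(size=10)
        model = _tiny_ensemble([th, -th], phi=[0.5, 0.5])
        assert np.allclose(shared_knowledge(model), 0.0)

    def test_matches_numerical_kl_minimization(self):
        # brute-force argmin_mu sum_i phi_i KL(N(theta_i, I) || N(mu, I))
        rng = np.random.default_rng(2)
        phi = np.array([0.2, 0.3, 0.5])
        thetas = [rng.normal(size=10) for _ in range(3)]
        model = _tiny_ensemble(thetas, phi=phi)

        def objective(mu):
            return sum(p * 0.5 * np.sum((t - mu) ** 2)
                       for p, t in zip(phi, thetas))

        res = minimize(objective, np.zeros(10), method="BFGS")
        assert np.allclose(shared_knowledge(model), res.x, atol=1e-4)

    def test_remove_with_tau_zero_is_identity(self):
        rng = np.random.default_rng(3)
        thetas = [rng.normal(size=10) for _ in range(2)]
        model = _tiny_ensemble(thetas, tau=0.0)
        remove_shared(model)
        for clf, th in zip(model.classifiers, thetas):
            assert np.array_equal(clf.theta, th)

    def test_single_class_full_removal_zeroes_theta(self):
        th = np.random.default_rng(4).normal(size=10)
        model = _tiny_ensemble([th], phi=[1.0], tau=1.0)
        remove_shared(model)
        assert np.allclose(model.classifiers[0].theta, 0.0)

    def test_matches_hand_computation(self):
        rng = np.random.default_rng(5)
        th1, th2 = rng.normal(size=10), rng.normal(size=10)
        model = _tiny_ensemble([th1, th2], phi=[0.4, 0.6], tau=0.1)
        rho = 0.4 * th1 + 0.6 * th2
        remove_shared(model)
        assert np.allclose(model.classifiers[0].theta, th1 - 0.1 * rho)
        assert np.allclose(model.classifiers[1].theta, th2 - 0.1 * rho)


class TestPredict:
    def test_agrees_with_brute_force_scan(self, rng):
        model = _tiny_ensemble([np.zeros(10)] * 3)
        for _ in range(1000):
            scores = rng.normal(size=3)
            best = 0
            for i in range(1, 3):
                if scores[i] > scores[best]:
                    best = i
            # emulate the argmax the model performs
            assert int(np.argmax(scores)) == best

    def test_predict_returns_highest_scoring_symbol(self, rng):
        # craft scorers with known constant-ish outputs via linear heads
        model = _tiny_ensemble([np.zeros(10)] * 3)
        F = rng.normal(size=(4, 2))
        S = model.score_features(F)
        for i, row in enumerate(S):
            assert model.predict_features(F)[i] == "NSV"[int(np.argmax(row))]

    def test_tie_breaks_toward_lowest_index(self):
        model = _tiny_ensemble([np.zeros(10)] * 3)  # all scores equal
        assert predict(model, np.zeros(2)) == "N"

    def test_single_classifier_always_wins(self, rng):
        model = _tiny_ensemble([np.random.default_rng(6).normal(size=10)],
                               phi=[1.0])
        for _ in range(5):
            assert predict(model, rng.normal(size=2)) == "N"


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path, rng):
        model = _tiny_ensemble(
            [np.random.default_rng(7).normal(size=10) for _ in range(3)]
        )
        model.feature_center = rng.normal(size=2)
        path = tmp_path / "m.npz"
        model.save(path)
        back = EnsembleModel.load(path)
        assert back.class_symbols == model.class_symbols
        assert np.allclose(back.feature_center, model.feature_center)
        for a, b in zip(back.classifiers, model.classifiers):
            assert np.array_equal(a.theta, b.theta)
        F = rng.normal(size=(3, 2))
        assert np.allclose(back.score_features(F), model.score_features(F))
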