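import math

import numpy as np
import pytest

import countlda as cl
from countlda.core import ClassLabels, CountMatrix, FittedModel
from countlda.estimation import LogisticZeroModel
from countlda.simulator import SimConfig, simulate_train_test
from conftest import degenerate_logistic, make_logistic, make_toy_model


def _two_class_model(method, d_vals, lam, phi=None, logistic=None,
                     priors=(0.5, 0.5)):
    return FittedModel(method=method, d=np.asarray(d_vals, dtype=float),
                       size_factors=np.array([0.5, 0.5]),
                       lam=np.asarray(lam, dtype=float),
                       priors=np.asarray(priors, dtype=float),
                       train_grand_total=100.0, ref_depth=50.0,
                       phi=None if phi is None else np.asarray(phi, dtype=float),
                       logistic=logistic)


class TestPoissonScore:
    def test_symmetric_null_predicts_first_class(self):
        model = _two_class_model("PLDA", np.ones((2, 3)), [1.0, 2.0, 3.0])
        out = cl.score_plda(np.array([1, 0, 4]), model, s_star=1.0)
        assert out.scores[0] == out.scores[1]
        assert out.predicted == 1

    def test_hand_evaluated_two_class_score(self):
        model = _two_class_model("PLDA", [[1.0], [2.0]], [2.0])
        out = cl.score_plda(np.array([3]), model, s_star=1.0)
        # d1 - d2 = 3(0 - log 2) - 1*(2 - 4) = 2 - 3 log 2
        assert out.scores[0] - out.scores[1] == pytest.approx(2 - 3 * math.log(2), abs=1e-12)
        assert out.predicted == 2


class TestNegativeBinomialScore:
    def test_hand_evaluated_score(self):
        model = _two_class_model("NBLDA", [[1.0], [2.0]], [2.0], phi=[1.0])
        out = cl.score_nblda(np.array([3]), model, s_star=1.0)
        # independent scalar arithmetic of the NB score at phi = 1
        d1 = 3 * (0 - math.log(3)) - math.log(3)
        d2 = 3 * (math.log(2) - math.log(5)) - math.log(5)
        assert out.scores[0] - out.scores[1] == pytest.approx(d1 - d2, abs=1e-12)

    def test_small_phi_close_to_poisson(self, rng):
        for _ in range(5):
            base = make_toy_model("PLDA", rng)
            nb = _clone(base, "NBLDA", phi=np.full(base.G, 1e-6))
            x = rng.poisson(2.0, base.G)
            sp = cl.score_plda(x, base, s_star=0.8).scores
            sn = cl.score_nblda(x, nb, s_star=0.8).scores
            assert np.max(np.abs(sp - sn)) <= 1e-3


def _clone(model, method, phi=None, logistic=None):
    return FittedModel(method=method, d=model.d, size_factors=model.size_factors,
                       lam=model.lam, priors=model.priors,
                       train_grand_total=model.train_grand_total,
                       ref_depth=model.ref_depth, phi=phi, logistic=logistic)


class TestZeroInflatedScores:
    def test_all_zero_vector_hand_value(self):
        # single gene, fixed p via intercept-only logistic
        lam, d1, d2, s_star = 2.0, 1.0, 2.0, 1.0
        model = _two_class_model("ZIPLDA", [[d1], [d2]], [lam],
                                 logistic=LogisticZeroModel(0.0, 0.0, 0.0, 50.0))
        out = cl.score_ziplda(np.array([0]), model, s_star=s_star)
        for k, d in enumerate((d1, d2)):
            mu = d * s_star * lam
            z = math.exp(-mu)
            p = (0.5 - z) / (1 - z)
            expected = math.log(p + (1 - p) * z) + math.log(0.5)
            assert out.scores[k] == pytest.approx(expected, abs=1e-12)

    def test_total_zero_inflation_leaves_only_priors(self):
        # alpha -> +inf: p-hat ~ 1 and an all-zero vector scores log(pi_k)
        model = _two_class_model("ZIPLDA", [[1.0], [2.0]], [2.0],
                                 logistic=LogisticZeroModel(60.0, 0.0, 0.0, 50.0),
                                 priors=(0.3, 0.7))
        out = cl.score_ziplda(np.array([0]), model, s_star=1.0)
        np.testing.assert_allclose(out.scores, np.log([0.3, 0.7]), atol=1e-9)
        assert out.predicted == 2


class TestLimitEquivalences:
    """The transformation square: each model reduces to its neighbours."""

    def test_exact_boundary_equalities(self, rng):
        for _ in range(10):
            base = make_toy_model("PLDA", rng)
            lg = make_logistic(rng)
            x = rng.poisson(2.0, base.G)
            s_star = float(rng.uniform(0.5, 1.5))
            phi = rng.uniform(0.2, 1.5, base.G)
            sp = cl.score_plda(x, base, s_star=s_star).scores
            # NBLDA at phi = 0 is PLDA
            nb0 = _clone(base, "NBLDA", phi=np.zeros(base.G))
            np.testing.assert_array_equal(cl.score_nblda(x, nb0, s_star=s_star).scores, sp)
            # ZIPLDA at p = 0 is PLDA
            zip0 = _clone(base, "ZIPLDA", logistic=degenerate_logistic())
            np.testing.assert_array_equal(cl.score_ziplda(x, zip0, s_star=s_star).scores, sp)
            # ZINBLDA at phi = 0 is ZIPLDA
            zp = _clone(base, "ZIPLDA", logistic=lg)
            znb0 = _clone(base, "ZINBLDA", phi=np.zeros(base.G), logistic=lg)
            np.testing.assert_array_equal(cl.score_zinblda(x, znb0, s_star=s_star).scores,
                                          cl.score_ziplda(x, zp, s_star=s_star).scores)
            # ZINBLDA at p = 0 is NBLDA
            nb = _clone(base, "NBLDA", phi=phi)
            znb = _clone(base, "ZINBLDA", phi=phi, logistic=degenerate_logistic())
            np.testing.assert_array_equal(cl.score_zinblda(x, znb, s_star=s_star).scores,
                                          cl.score_nblda(x, nb, s_star=s_star).scores)


class TestOracle:
    """Scores equal the literal log product of per-gene pmfs + log prior,
    up to a class-independent constant, for tiny models."""

    def test_against_brute_force(self, rng):
        from scipy.stats import nbinom, poisson
        from scipy.special import expit

        for method in cl.METHODS:
            for _ in range(5):
                phi = rng.uniform(0.2, 1.5, 3) if method in ("NBLDA", "ZINBLDA") else None
                lg = make_logistic(rng) if method in ("ZIPLDA", "ZINBLDA") else None
                model = make_toy_model(method, rng, K=2, G=3, phi=phi, logistic=lg)
                x = np.minimum(rng.poisson(2.0, 3), 5)
                s_star = float(rng.uniform(0.5, 1.5))
                depth = float(x.sum())
                scores = getattr(cl, f"score_{method.lower()}")(x, model, s_star=s_star).scores
                oracle = np.empty(2)
                for k in range(2):
                    mu = model.d[k] * s_star * model.lam
                    ph = phi if phi is not None else np.zeros(3)
                    if lg is not None:
                        eta = lg.alpha + lg.beta1 * depth / lg.ref_depth + lg.beta2 * mu
                        z = np.where(ph > 0,
                                     (1 + mu * np.where(ph > 0, ph, 1)) ** (-1 / np.where(ph > 0, ph, 1)),
                                     np.exp(-mu))
                        p = np.clip((expit(eta) - z) / (1 - z), 0.0, 1.0 - 1e-12)
                    else:
                        p = np.zeros(3)
                    ll = 0.0
                    for g in range(3):
                        if ph[g] > 0:
                            r = 1.0 / ph[g]
                            base_pmf = nbinom.pmf(x[g], r, r / (r + mu[g]))
                        else:
                            base_pmf = poisson.pmf(x[g], mu[g])
                        if x[g] == 0:
                            ll += math.log(p[g] + (1 - p[g]) * base_pmf)
                        else:
                            ll += math.log((1 - p[g]) * base_pmf)
                    oracle[k] = ll + math.log(model.priors[k])
                np.testing.assert_allclose(scores - scores[0], oracle - oracle[0],
                                           atol=1e-10)


class TestFitAndPredict:
    def test_method_contracts(self, toy_counts):
        counts, labels = toy_counts
        plda = cl.fit(counts, labels, "PLDA")
        assert plda.phi is None and plda.logistic is None
        np.testing.assert_allclose(plda.priors, [0.5, 0.5])
        zinb = cl.fit(counts, labels, "ZINBLDA")
        assert zinb.phi is not None and zinb.logistic is not None

    def test_zero_free_matrix_reduces_to_nblda(self):
        rng = np.random.default_rng(3)
        X = rng.poisson(20.0, size=(30, 20)) + 1       # strictly positive
        counts = CountMatrix(X)
        labels = ClassLabels(np.array([1] * 10 + [2] * 10))
        zinb = cl.fit(counts, labels, "ZINBLDA", phi_tol=1e-4)
        nb = cl.fit(counts, labels, "NBLDA", phi_tol=1e-4)
        assert zinb.logistic.degenerate
        test = rng.poisson(20.0, size=(30, 8)) + 1
        np.testing.assert_array_equal(cl.predict(test, zinb)[0], cl.predict(test, nb)[0])

    def test_resubstitution_error_low_in_separable_regime(self):
        cfg = SimConfig(n=40, G=100, phi=0.0, p0=0.0, sigma=0.6, de_rate=0.3, seed=5)
        train, _ = simulate_train_test(cfg)
        model = cl.fit(train.counts, train.labels, "PLDA")
        pred, _ = cl.predict(train.counts, model)
        assert cl.evaluate(pred, train.labels.labels) <= 0.05

    def test_tie_break_smallest_class(self):
        model = _two_class_model("PLDA", np.ones((2, 2)), [1.0, 1.0])
        pred, scores = cl.predict(np.array([[1, 2], [0, 1]]), model, s_star=[1.0, 1.0])
        assert np.all(scores[:, 0] == scores[:, 1])
        assert np.all(pred == 1)

    def test_class_permutation_equivariance(self, rng):
        model = make_toy_model("PLDA", rng, K=3, G=4)
        X = rng.poisson(2.0, size=(4, 6))
        s = np.full(6, 0.9)
        pred, _ = cl.predict(X, model, s_star=s)
        perm = np.array([2, 0, 1])        # new index of old class k
        permuted = FittedModel(method="PLDA", d=model.d[np.argsort(perm)],
                               size_factors=model.size_factors, lam=model.lam,
                               priors=model.priors[np.argsort(perm)],
                               train_grand_total=model.train_grand_total,
                               ref_depth=model.ref_depth)
        pred2, _ = cl.predict(X, permuted, s_star=s)
        assert np.all(pred2 == perm[pred - 1] + 1)

    def test_prior_dominance(self, rng):
        priors = np.array([1e-9, 1.0 - 1e-9])
        model = make_toy_model("PLDA", rng, K=2, G=2, priors=priors)
        x = rng.poisson(1.0, 2)           # bounded scores
        assert cl.score_plda(x, model, s_star=1.0).predicted == 2

    def test_gene_dimension_mismatch(self, rng):
        model = make_toy_model("PLDA", rng, G=3)
        with pytest.raises(ValueError, match="genes"):
            cl.predict(np.zeros((5, 2), dtype=int), model, s_star=[1.0, 1.0])
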