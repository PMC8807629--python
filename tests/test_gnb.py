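import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import survclass as sc
from survclass.gnb import (
    GNBModel,
    apply_preprocessing,
    class_weight_vectors,
    log_posterior_matrix,
)


def _model(means, variances, priors=(0.5, 0.5), preprocessing="none"):
    means = np.asarray(means, dtype=float)
    d = means.shape[1]
    return GNBModel(
        classes=("A", "B"),
        priors=np.asarray(priors, dtype=float),
        gene_ids=[f"g{i}" for i in range(d)],
        means=means,
        variances=np.asarray(variances, dtype=float),
        preprocessing=preprocessing,
    )


class TestTransformLikelihood:
    def test_identity_at_d1(self):
        assert sc.transform_likelihood([0.3]) == pytest.approx(0.3)

    def test_constant_inputs(self):
        for d in (2, 7, 100):
            assert sc.transform_likelihood([0.42] * d) == pytest.approx(0.42)

    def test_uniform_expectation_closed_form(self):
        # oracle: E[(prod u_i)^(1/d)] = (1 / (1 + 1/d))^d
        d, n = 10, 10**6
        u = sc.sample_uniform_likelihoods(d, n, seed=0)
        geo = np.exp(np.mean(np.log(u), axis=1))
        expected = (1.0 / (1.0 + 1.0 / d)) ** d
        assert expected == pytest.approx(0.3855, abs=1e-4)
        assert abs(geo.mean() - expected) < 0.002

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            sc.transform_likelihood([0.5, -0.1])
        with pytest.raises(ValueError):
            sc.transform_likelihood([0.5, np.inf])

    def test_never_forms_raw_product(self):
        # d large enough that the raw product underflows to exactly 0
        likes = np.full(1408, 0.5)
        assert np.prod(likes) == 0.0
        assert sc.transform_likelihood(likes) == pytest.approx(0.5)


@settings(max_examples=50, deadline=None)
@given(
    st.lists(
        st.floats(min_value=1e-10, max_value=1.0),
        min_size=2,
        max_size=20,
    ),
    st.integers(min_value=0, max_value=19),
)
def test_transform_strictly_monotone_per_argument(likes, pos):
    pos = pos % len(likes)
    base = sc.transform_likelihood(likes)
    likes2 = list(likes)
    likes2[pos] = min(likes2[pos] * 1.5 + 1e-9, 2.0)
    assert sc.transform_likelihood(likes2) > base


class TestGaussianLikelihood:
    def test_density_at_the_mean(self):
        m = _model([[0.0, 1.0], [5.0, 5.0]], [[1.0, 1.0], [1.0, 1.0]])
        vals = sc.gaussian_likelihood(m, [0.0, 1.0], 0)
        np.testing.assert_allclose(vals, 1.0 / np.sqrt(2 * np.pi))

    def test_symmetric_classes_at_zero(self):
        m = _model([[1.0, 1.0], [-1.0, -1.0]], np.ones((2, 2)))
        a = sc.gaussian_likelihood(m, [0.0, 0.0], 0)
        b = sc.gaussian_likelihood(m, [0.0, 0.0], 1)
        np.testing.assert_allclose(a, b)

    def test_standard_normal_table(self):
        # N(0,1) density at 1 and 2: 0.2420, 0.0540
        m = _model([[0.0, 0.0], [9.0, 9.0]], np.ones((2, 2)))
        vals = sc.gaussian_likelihood(m, [1.0, 2.0], 0)
        np.testing.assert_allclose(vals, [0.2420, 0.0540], atol=5e-5)

    def test_dimension_mismatch(self):
        m = _model([[0.0, 0.0], [1.0, 1.0]], np.ones((2, 2)))
        with pytest.raises(ValueError, match="length 2"):
            sc.gaussian_likelihood(m, [0.0, 0.0, 0.0], 0)


class TestPosterior:
    def test_symmetry_returns_priors(self):
        m = _model([[0.0], [0.0]], [[1.0], [1.0]], priors=(0.5, 0.5))
        np.testing.assert_allclose(sc.posterior(m, [0.7]), [0.5, 0.5])

    def test_bayes_rule_at_d1(self):
        # d=1: the transform is the identity, so a 1:3 likelihood ratio
        # with flat priors gives (0.25, 0.75) exactly as in plain Bayes.
        mu_a = np.sqrt(2.0 * np.log(3.0))  # density ratio at x=0 is 1/3
        m = _model([[mu_a], [0.0]], [[1.0], [1.0]])
        post = sc.posterior(m, [0.0])
        np.testing.assert_allclose(post, [0.25, 0.75], atol=1e-12)

    def test_unequal_priors(self):
        m = _model([[0.0], [0.0]], [[1.0], [1.0]], priors=(0.25, 0.75))
        np.testing.assert_allclose(sc.posterior(m, [1.3]), [0.25, 0.75])

    def test_high_dimension_not_saturated(self):
        d = 1408
        rng = np.random.default_rng(0)
        means = np.vstack([np.full(d, 0.5), np.full(d, -0.5)])
        m = _model(means, np.ones((2, d)))
        x = rng.normal(0.5, 1.0, d)  # drawn from class A
        post = sc.posterior(m, x)
        assert 0.0 < post[0] < 1.0 and 0.0 < post[1] < 1.0
        assert post[0] > post[1]
        # the raw per-gene likelihood product underflows double precision
        raw = np.prod(sc.gaussian_likelihood(m, x, 0))
        assert raw == 0.0

    def test_sums_to_one(self):
        rng = np.random.default_rng(1)
        m = _model(rng.normal(size=(2, 30)), np.ones((2, 30)) * 0.5,
                   priors=(0.3, 0.7))
        post = sc.posterior(m, rng.normal(size=30))
        assert post.sum() == pytest.approx(1.0, abs=1e-12)


class TestClassify:
    def test_argmax(self):
        m = _model([[0.0], [4.0]], [[1.0], [1.0]])
        assert sc.classify(m, [0.1]) == "A"
        assert sc.classify(m, [3.9]) == "B"

    def test_tie_goes_to_first_class(self):
        m = _model([[1.0], [-1.0]], [[1.0], [1.0]])
        assert sc.classify(m, [0.0]) == "A"

    def test_high_separation_training_accuracy(self):
        # 2 SD effect, d=60, n=200/class: near-perfect separability
        rng = np.random.default_rng(42)
        d, n = 60, 200
        mu = rng.uniform(4, 10, d)
        Xa = rng.normal(mu[:, None] + 1.0, 1.0, (d, n))
        Xb = rng.normal(mu[:, None] - 1.0, 1.0, (d, n))
        X = np.exp2(np.concatenate([Xa, Xb], axis=1))
        labels = np.array(["A"] * n + ["B"] * n)
        model = sc.fit_gnb(
            X, labels, [f"g{i}" for i in range(d)], ("A", "B"),
            use_soft_weights=False,
        )
        logpost = log_posterior_matrix(model, X)
        pred = np.where(logpost[0] >= logpost[1], "A", "B")
        assert (pred == labels).mean() >= 0.95

    def test_order_preserved_vs_untransformed_log_space(self):
        # equal priors: the d-th root preserves the likelihood ordering,
        # so argmax matches the untransformed classifier computed in log
        # space (with unequal priors the two classifiers legitimately
        # differ: the root shrinks the likelihood's influence).
        rng = np.random.default_rng(3)
        for d in (2, 10, 50):
            m = _model(
                rng.normal(size=(2, d)),
                rng.uniform(0.5, 2.0, size=(2, d)),
            )
            for _ in range(20):
                x = rng.normal(size=d)
                full = [
                    np.sum(np.log(sc.gaussian_likelihood(m, x, k)))
                    for k in range(2)
                ]
                untransformed = "A" if full[0] >= full[1] else "B"
                assert sc.classify(m, x) == untransformed


class TestLogisticLink:
    def test_midpoint_is_half(self):
        link = sc.fit_logistic_link(
            np.array([10.0, 12.0, 2.0, 4.0]),
            np.array([True, True, False, False]),
        )
        assert link.prob_first(link.b) == pytest.approx(0.5)

    def test_hand_computed_coefficients(self):
        # mu_long=100, mu_short=20, pooled var 400 -> a=-0.2, b=60
        rng = np.random.default_rng(0)
        y_long = 100.0 + np.array([-20.0, 20.0])
        y_short = 20.0 + np.array([-20.0, 20.0])
        y = np.concatenate([y_long, y_short])
        is_long = np.array([True, True, False, False])
        link = sc.fit_logistic_link(y, is_long)
        assert link.a == pytest.approx(-0.2)
        assert link.b == pytest.approx(60.0)
        assert link.prob_first(100.0) == pytest.approx(
            1.0 / (1.0 + np.exp(-0.2 * 40.0))
        )
        assert link.prob_first(100.0) == pytest.approx(0.99966, abs=5e-5)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(1)
        y = rng.exponential(10, 40)
        is_long = y > np.median(y)
        link = sc.fit_logistic_link(y, is_long)
        swapped = sc.fit_logistic_link(y, ~is_long)
        assert swapped.a == pytest.approx(-link.a)
        np.testing.assert_allclose(
            link.prob_first(y) + swapped.prob_first(y), 1.0
        )

    def test_increasing_in_y_for_long_class(self):
        rng = np.random.default_rng(2)
        y = np.concatenate(
            [rng.exponential(100, 50), rng.exponential(10, 50)]
        )
        is_long = np.concatenate([np.ones(50, bool), np.zeros(50, bool)])
        link = sc.fit_logistic_link(y, is_long)
        grid = np.linspace(0, 200, 50)
        assert np.all(np.diff(link.prob_first(grid)) > 0)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="non-empty"):
            sc.fit_logistic_link(np.ones(3), np.array([True, True, True]))
        with pytest.raises(ValueError, match="variance"):
            sc.fit_logistic_link(
                np.array([5.0, 5.0]), np.array([True, False])
            )


class TestWeightedClassParams:
    def test_hand_arithmetic(self):
        m, v = sc.weighted_class_params([1.0, 3.0], [0.25, 0.75])
        assert m == pytest.approx(2.5)
        assert v == pytest.approx(0.75)

    def test_hard_weights_recover_class_moments(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        members = np.zeros(20)
        members[:8] = 1.0 / 8.0
        m, v = sc.weighted_class_params(x, members)
        assert m == pytest.approx(x[:8].mean())
        assert v == pytest.approx(x[:8].var())  # biased variance

    def test_uniform_weights_are_global_moments(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=15)
        m, v = sc.weighted_class_params(x, np.full(15, 1 / 15))
        assert m == pytest.approx(x.mean())
        assert v == pytest.approx(x.var())

    def test_unnormalized_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            sc.weighted_class_params([1.0, 2.0], [0.5, 0.6])


class TestFitGNB:
    def test_priors_are_label_frequencies(self):
        rng = np.random.default_rng(0)
        X = np.exp2(rng.normal(5, 1, (4, 400)))
        labels = np.array(["A"] * 300 + ["B"] * 100)
        y = np.concatenate([rng.exponential(50, 300),
                            rng.exponential(5, 100)])
        model = sc.fit_gnb(X, labels, list("abcd"), ("A", "B"), y=y)
        np.testing.assert_allclose(model.priors, [0.75, 0.25])

    def test_separated_y_soft_equals_hard(self):
        rng = np.random.default_rng(1)
        X = np.exp2(rng.normal(5, 1, (6, 100)))
        labels = np.array(["A"] * 50 + ["B"] * 50)
        y = np.concatenate([np.full(50, 1000.0) + rng.normal(0, 1, 50),
                            np.full(50, 1.0) + rng.normal(0, 0.01, 50)])
        soft = sc.fit_gnb(X, labels, list("abcdef"), ("A", "B"), y=y,
                          use_soft_weights=True)
        hard = sc.fit_gnb(X, labels, list("abcdef"), ("A", "B"),
                          use_soft_weights=False)
        np.testing.assert_allclose(soft.means, hard.means, atol=1e-6)
        np.testing.assert_allclose(soft.variances, hard.variances, atol=1e-5)

    def test_parameter_recovery_hard_mode(self):
        # planted 1 SD log2 difference, n=500/class; the per-gene
        # mean-difference estimator has sd ~= sqrt(2/500) ~= 0.063, so
        # ~89% of genes land within +-0.1 and ~99.8% within +-0.2
        rng = np.random.default_rng(42)
        G, n = 60, 500
        mu = rng.uniform(4, 10, G)
        Xa = rng.normal(mu[:, None] + 0.5, 1.0, (G, n))
        Xb = rng.normal(mu[:, None] - 0.5, 1.0, (G, n))
        X = np.exp2(np.concatenate([Xa, Xb], axis=1))
        labels = np.array(["A"] * n + ["B"] * n)
        model = sc.fit_gnb(
            X, labels, [f"g{i}" for i in range(G)], ("A", "B"),
            use_soft_weights=False,
        )
        diff = model.means[0] - model.means[1]
        assert (np.abs(diff - 1.0) < 0.1).mean() >= 0.8
        assert (np.abs(diff - 1.0) < 0.2).mean() >= 0.95

    def test_constant_gene_floored_with_warning(self):
        X = np.vstack([np.full(40, 8.0), np.exp2(np.random.default_rng(0)
                                                 .normal(5, 1, 40))])
        labels = np.array(["A"] * 20 + ["B"] * 20)
        with pytest.warns(RuntimeWarning, match="floored"):
            model = sc.fit_gnb(X, labels, ["flat", "ok"], ("A", "B"),
                               use_soft_weights=False)
        assert model.variances[0, 0] == pytest.approx(1e-6)


@settings(max_examples=40, deadline=None)
@given(st.floats(min_value=0.01, max_value=100.0))
def test_posterior_invariant_to_common_likelihood_rescaling(scale):
    # P(C|x) built from transformed likelihoods is unchanged when both
    # classes' likelihood vectors are rescaled by the same factor
    likes_a = np.array([0.1, 0.4, 0.8])
    likes_b = np.array([0.3, 0.2, 0.5])
    priors = np.array([0.4, 0.6])

    def post(la, lb):
        ta = sc.transform_likelihood(la) * priors[0]
        tb = sc.transform_likelihood(lb) * priors[1]
        return ta / (ta + tb)

    assert post(likes_a * scale, likes_b * scale) == pytest.approx(
        post(likes_a, likes_b), rel=1e-9
    )


def test_apply_preprocessing_roundtrip():
    x = np.array([0.0, 1.0, 3.0])
    np.testing.assert_allclose(
        apply_preprocessing(x, "log2p1"), np.log2(x + 1.0)
    )
    np.testing.assert_allclose(apply_preprocessing(x, "none"), x)
    with pytest.raises(ValueError):
        apply_preprocessing(x, "sqrt")


def test_class_weight_vectors_normalised():
    rng = np.random.default_rng(0)
    y = rng.exponential(10, 30)
    labels = np.where(y > np.median(y), "L", "S")
    for soft in (True, False):
        w = class_weight_vectors(labels, ("L", "S"), y=y,
                                 use_soft_weights=soft)
        np.testing.assert_allclose(w.sum(axis=1), [1.0, 1.0], atol=1e-12)
        assert (w >= 0).all()
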