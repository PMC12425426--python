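"""Shapley axioms against brute-force oracles, sampling convergence, LIME
surrogates and importance-ranking comparisons."""

import itertools
import math

import numpy as np
import pytest

from actidep.explain import (
    BackgroundReference,
    ImportanceRanking,
    LimeTabularExplainer,
    compare_model_explanations,
    exact_shapley,
    global_importance,
    lime_explain,
    sampled_shapley,
)


def brute_force_shapley(model_fn, x, background, i):
    """Independent subset-enumeration oracle for one feature's phi_i."""
    p = len(x)
    others = [j for j in range(p) if j != i]

    def value(subset):
        rows = background.copy()
        for j in subset:
            rows[:, j] = x[j]
        return float(np.mean(model_fn(rows)))

    phi = 0.0
    for r in range(p):
        for subset in itertools.combinations(others, r):
            w = (math.factorial(len(subset))
                 * math.factorial(p - len(subset) - 1) / math.factorial(p))
            phi += w * (value(subset + (i,)) - value(subset))
    return phi


class TestExactShapley:
    def test_linear_model_closed_form_and_oracle(self, rng):
        """For f(x) = w.x with a single baseline b, phi_i = w_i (x_i - b_i);
        both the closed form and a brute-force enumeration must agree."""
        w = np.array([2.0, -1.0, 0.5, 3.0])
        fn = lambda X: X @ w
        x = np.array([1.0, 2.0, -1.0, 0.5])
        b = np.array([[0.5, 0.5, 0.5, 0.5]])
        exp = exact_shapley(fn, x, b)
        np.testing.assert_allclose(exp.phi, w * (x - b[0]), atol=1e-10)
        for i in range(4):
            assert exp.phi[i] == pytest.approx(
                brute_force_shapley(fn, x, b, i), abs=1e-10
            )

    def test_dummy_feature_gets_zero(self, rng):
        fn = lambda X: X[:, 0] ** 2 + np.sin(X[:, 2])
        x = rng.normal(0, 1, 4)
        bg = rng.normal(0, 1, (10, 4))
        exp = exact_shapley(fn, x, bg)
        assert exp.phi[1] == pytest.approx(0.0, abs=1e-12)
        assert exp.phi[3] == pytest.approx(0.0, abs=1e-12)

    def test_efficiency_for_nonlinear_model(self, rng):
        fn = lambda X: np.tanh(X @ np.array([1.0, -2.0, 0.5])) + X[:, 0] * X[:, 1]
        x = rng.normal(0, 1, 3)
        bg = rng.normal(0, 1, (20, 3))
        exp = exact_shapley(fn, x, bg)
        v_empty = float(np.mean(fn(bg)))
        assert exp.phi.sum() == pytest.approx(exp.fx - v_empty, abs=1e-8)
        assert exp.base_value == pytest.approx(v_empty, abs=1e-12)

    def test_symmetric_features_get_equal_phi(self, rng):
        fn = lambda X: X[:, 0] + X[:, 1] + 0.3 * X[:, 0] * X[:, 1]
        x = np.array([1.2, 1.2, -0.4])
        bg = np.zeros((1, 3))
        exp = exact_shapley(fn, x, bg)
        assert exp.phi[0] == pytest.approx(exp.phi[1], abs=1e-12)

    def test_additive_model_single_baseline_recovers_components(self):
        comps = [lambda v: v**2, lambda v: np.sin(v), lambda v: 3 * v]
        fn = lambda X: sum(c(X[:, i]) for i, c in enumerate(comps))
        x = np.array([1.5, 0.7, -2.0])
        b = np.zeros((1, 3))
        exp = exact_shapley(fn, x, b)
        expected = [c(np.array([xi]))[0] - c(np.array([0.0]))[0]
                    for xi, c in zip(x, comps)]
        np.testing.assert_allclose(exp.phi, expected, atol=1e-10)

    def test_p_limit_directs_to_sampling(self, rng):
        x = rng.normal(0, 1, 6)
        bg = rng.normal(0, 1, (5, 6))
        with pytest.raises(ValueError, match="sampled_shapley"):
            exact_shapley(lambda X: X.sum(axis=1), x, bg, p_limit=4)


class TestSampledShapley:
    def test_converges_to_exact_oracle(self, rng):
        """At p = 6 the permutation estimate must approach the enumerated
        value to within 2% of the model's output range."""
        w = rng.normal(0, 1, 6)
        fn = lambda X: X @ w + 0.5 * X[:, 0] * X[:, 1]
        x = rng.normal(0, 1, 6)
        bg = rng.normal(0, 1, (5, 6))
        exact = exact_shapley(fn, x, bg)
        est = sampled_shapley(fn, x, bg, n_permutations=10_000, seed=1)
        out_range = np.ptp(fn(rng.normal(0, 1, (500, 6))))
        assert np.max(np.abs(est.phi - exact.phi)) < 0.02 * out_range
        assert est.renormalized

    def test_same_seed_identical(self, rng):
        fn = lambda X: X.sum(axis=1) ** 2
        x = rng.normal(0, 1, 5)
        bg = rng.normal(0, 1, (4, 5))
        a = sampled_shapley(fn, x, bg, n_permutations=50, seed=9)
        b = sampled_shapley(fn, x, bg, n_permutations=50, seed=9)
        np.testing.assert_array_equal(a.phi, b.phi)

    def test_efficiency_enforced(self, rng):
        fn = lambda X: np.exp(X[:, 0]) + X[:, 1] * X[:, 2]
        x = rng.normal(0, 1, 3)
        bg = rng.normal(0, 1, (8, 3))
        est = sampled_shapley(fn, x, bg, n_permutations=20, seed=2)
        assert est.phi.sum() == pytest.approx(est.fx - est.base_value,
                                              abs=1e-10)

    def test_error_nonincreasing_with_more_permutations(self, rng):
        """Mean squared deviation from the exact values, averaged over 20
        seeds, must not grow when the permutation budget doubles."""
        w = np.array([1.0, -2.0, 0.5, 1.5])
        fn = lambda X: X @ w + X[:, 0] * X[:, 3]
        x = np.array([0.8, -0.3, 1.1, 0.4])
        bg = rng.normal(0, 1, (5, 4))
        exact = exact_shapley(fn, x, bg)

        def mse(n_perm):
            errs = []
            for seed in range(20):
                est = sampled_shapley(fn, x, bg, n_permutations=n_perm,
                                      seed=seed)
                errs.append(np.mean((est.phi - exact.phi) ** 2))
            return np.mean(errs)

        assert mse(160) <= mse(40)


class TestLime:
    def test_constant_model_gives_zero_weights(self, rng):
        fn = lambda X: np.full(len(X), 0.6)
        training = rng.normal(0, 1, (200, 4))
        exp = lime_explain(fn, training[0], training, n_samples=500, seed=0)
        assert all(abs(w) < 1e-6 for _, w in exp.rules)
        assert exp.intercept == pytest.approx(0.6, abs=1e-6)

    def test_monotone_model_rule_sign_matches_direction(self, rng):
        """For an increasing single-feature model explained at a top-quartile
        instance, membership of that bin must carry positive weight."""
        fn = lambda X: 2.0 * X[:, 0]
        training = rng.normal(0, 1, (500, 1))
        x = np.array([training[:, 0].max()])  # top bin
        exp = lime_explain(fn, x, training, feature_names=["act"],
                           n_samples=2000, seed=0)
        rule, weight = exp.rules[0]
        assert "act" in rule and weight > 0
        assert exp.r_squared > 0.5

    def test_fixed_seed_reproducible(self, rng):
        fn = lambda X: X[:, 0] - X[:, 1] ** 2
        training = rng.normal(0, 1, (300, 3))
        a = lime_explain(fn, training[5], training, n_samples=800, seed=4)
        b = lime_explain(fn, training[5], training, n_samples=800, seed=4)
        assert a.rules == b.rules
        assert a.r_squared == b.r_squared

    def test_degenerate_feature_excluded_with_warning(self, rng):
        fn = lambda X: X[:, 0]
        training = np.column_stack([rng.normal(0, 1, 300),
                                    np.full(300, 2.0)])
        with pytest.warns(UserWarning, match="degenerate"):
            exp = lime_explain(fn, training[0], training,
                               feature_names=["a", "const"], n_samples=400,
                               seed=0)
        assert exp.excluded_features == ["const"]
        assert all("const" not in rule for rule, _ in exp.rules)

    def test_explainer_class_wrapper(self, rng):
        fn = lambda X: X[:, 1]
        training = rng.normal(0, 1, (200, 3))
        explainer = LimeTabularExplainer(fn, n_samples=500, seed=3).fit(
            training, feature_names=["a", "b", "c"]
        )
        exp = explainer.explain(training[0])
        assert exp.rules and exp.n_samples == 500


class TestImportance:
    def _explanations(self, phis, names):
        from actidep.explain import ShapleyExplanation

        return [
            ShapleyExplanation(instance_id=str(i), phi=np.asarray(phi),
                               base_value=0.0, fx=float(np.sum(phi)),
                               feature_names=names)
            for i, phi in enumerate(phis)
        ]

    def test_single_explanation_ranks_by_abs_phi(self):
        exps = self._explanations([[0.1, -0.5, 0.3]], ["a", "b", "c"])
        rank = global_importance(exps)
        assert rank.feature_names == ["b", "c", "a"]
        np.testing.assert_allclose(rank.importance, [0.5, 0.3, 0.1])

    def test_permutation_invariant(self, rng):
        phis = rng.normal(0, 1, (10, 4)).tolist()
        names = ["a", "b", "c", "d"]
        a = global_importance(self._explanations(phis, names))
        b = global_importance(self._explanations(phis[::-1], names))
        assert a.feature_names == b.feature_names
        np.testing.assert_allclose(a.importance, b.importance)

    def test_identical_rankings_agree_fully(self):
        a = ImportanceRanking(["x", "y", "z"], np.array([3.0, 2.0, 1.0]), "m1")
        b = ImportanceRanking(["x", "y", "z"], np.array([0.3, 0.2, 0.1]), "m2")
        cmp = compare_model_explanations(a, b, top_k=3)
        assert cmp["spearman_rho"] == pytest.approx(1.0)
        assert cmp["top_k_overlap"] == 3
        assert all(v == 0 for v in cmp["rank_deltas"].values())

    def test_reversed_rankings_anticorrelate(self):
        a = ImportanceRanking(["x", "y", "z"], np.array([3.0, 2.0, 1.0]))
        b = ImportanceRanking(["x", "y", "z"], np.array([1.0, 2.0, 3.0]))
        assert compare_model_explanations(a, b)["spearman_rho"] == pytest.approx(-1.0)

    def test_mismatched_feature_sets_rejected(self):
        a = ImportanceRanking(["x", "y"], np.array([1.0, 2.0]))
        b = ImportanceRanking(["x", "q"], np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="different feature sets"):
            compare_model_explanations(a, b)

    def test_deterministic_training_gives_identical_top3(self, rng):
        """Two boosted models trained with the same seed on the same data
        must produce identical importance rankings."""
        from actidep.explain import PermutationShapleyExplainer
        from actidep.model_eval import train_classifier

        X = rng.normal(0, 1, (150, 5))
        y = (X[:, 0] + 0.5 * X[:, 3] > 0).astype(int)
        ranks = []
        for _ in range(2):
            model = train_classifier("gradient_boosting", X, y,
                                     {"n_estimators": 50}, seed=3)
            fn = lambda d: model.predict_proba(np.asarray(d))[:, 1]
            ex = PermutationShapleyExplainer(fn, n_permutations=30,
                                             seed=3).fit(X[:20])
            exps = [ex.explain(X[i]) for i in range(10)]
            ranks.append(global_importance(exps, "gb"))
        assert ranks[0].top(3) == ranks[1].top(3)


def test_background_reference_validation():
    with pytest.raises(ValueError, match="non-empty"):
        BackgroundReference(np.empty((0, 3)))
    ref = BackgroundReference.subsample(np.random.default_rng(0).normal(
        0, 1, (100, 4)), size=10, seed=1)
    assert ref.rows.shape == (10, 4)
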