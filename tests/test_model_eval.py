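"""Classifier roster, metric suite oracle, CV protocol and significance."""

import numpy as np
import pandas as pd
import pytest

from actidep.model_eval import (
    MODEL_NAMES,
    ConfusionMatrix,
    confusion,
    holm_adjust,
    make_classifier,
    metric_suite,
    paired_t_test,
    participant_folds,
    repeated_stratified_cv,
    significance_protocol,
    train_classifier,
)


def hand_metric_oracle(tp, fp, fn, tn):
    """Independent cell-by-cell evaluation of the standard formulas."""
    total = tp + fp + fn + tn
    acc = (tp + tn) / total if total else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    den = ((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)) ** 0.5
    mcc = (tp * tn - fp * fn) / den if den else 0.0
    return acc, prec, rec, spec, f1, mcc


class TestClassifiers:
    def _blobs(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(-3, 0.5, (n, 4)), rng.normal(3, 0.5, (n, 4))])
        y = np.array([0] * n + [1] * n)
        return X, y

    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_separable_blobs_fit_perfectly(self, name):
        X, y = self._blobs()
        model = train_classifier(name, X, y, seed=0)
        assert (model.predict(X) == y).mean() == 1.0
        proba = model.predict_proba(X)
        assert proba.shape == (len(y), 2)

    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_same_seed_identical_predictions(self, name):
        X, y = self._blobs(seed=1)
        rng = np.random.default_rng(5)
        Xq = rng.normal(0, 3, (50, 4))
        a = train_classifier(name, X, y, seed=7).predict_proba(Xq)
        b = train_classifier(name, X, y, seed=7).predict_proba(Xq)
        np.testing.assert_array_equal(a, b)

    def test_multiclass_strategy_options(self, rng):
        X = np.vstack([rng.normal(c, 0.4, (40, 3)) for c in (-3, 0, 3)])
        y = np.repeat([0, 1, 2], 40)
        for name, hp in [("logistic", {"multi_class": "ovr"}),
                         ("logistic", {"multi_class": "multinomial"}),
                         ("svm", {"decision_shape": "ovo"})]:
            model = train_classifier(name, X, y, hp, seed=0)
            assert (model.predict(X) == y).mean() == 1.0
            assert model.predict_proba(X).shape == (120, 3)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            make_classifier("perceptron")

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            train_classifier("logistic", np.zeros((5, 2)), np.zeros(5))

    def test_permuted_labels_give_chance_level_cv(self):
        """A null model on label-permuted balanced data must score near 0.5."""
        rng = np.random.default_rng(11)
        n = 500
        X = rng.normal(0, 1, (n, 5))
        y = rng.permutation([0] * (n // 2) + [1] * (n // 2))
        frame = pd.DataFrame(X, columns=list("abcde"))
        pids = np.array([f"p{i}" for i in range(n)])  # one window each
        res = repeated_stratified_cv(["logistic"], frame, y, pids,
                                     repeats=1, k=5, seed=3)
        acc = np.trace(res["logistic"].pooled_confusion.matrix) / n
        assert acc == pytest.approx(0.5, abs=0.1)


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self):
        y = [0, 1, 2, 1, 0, 2]
        cm = confusion(y, y, classes=[0, 1, 2])
        assert np.all(cm.matrix == np.diag([2, 2, 2]))

    def test_all_positive_predictions(self):
        cm = confusion([0, 0, 1, 1], [1, 1, 1, 1], classes=[0, 1])
        tp, fp, fn, tn = cm.binary_cells()
        assert (tp, fp, fn, tn) == (2, 2, 0, 0)

    def test_hand_tally_of_ten_pairs(self):
        y_true = [1, 0, 1, 1, 0, 0, 1, 0, 1, 1]
        y_pred = [1, 0, 0, 1, 1, 0, 1, 0, 0, 1]
        cm = confusion(y_true, y_pred, classes=[0, 1])
        # hand count: TP pairs (1,1) = 4; FN (1,0) = 2; FP (0,1) = 1; TN = 3
        assert cm.binary_cells() == (4, 1, 2, 3)

    def test_label_outside_class_set_rejected(self):
        with pytest.raises(ValueError, match="outside class set"):
            confusion([0, 1], [0, 2], classes=[0, 1])


class TestMetricSuite:
    def test_perfect_classifier(self):
        cm = ConfusionMatrix.from_binary_cells(tp=50, fp=0, fn=0, tn=50)
        rep = metric_suite(cm)
        assert rep.accuracy == rep.precision == rep.recall == 1.0
        assert rep.specificity == rep.f1 == rep.mcc == 1.0

    def test_chance_classifier(self):
        cm = ConfusionMatrix.from_binary_cells(tp=25, fp=25, fn=25, tn=25)
        rep = metric_suite(cm)
        assert rep.accuracy == 0.5 and rep.mcc == 0.0

    def test_worked_example(self):
        cm = ConfusionMatrix.from_binary_cells(tp=40, fp=10, fn=5, tn=45)
        rep = metric_suite(cm)
        assert rep.accuracy == pytest.approx(0.85)
        assert rep.precision == pytest.approx(0.8)
        assert rep.recall == pytest.approx(0.8889, abs=1e-4)
        assert rep.specificity == pytest.approx(0.8182, abs=1e-4)
        assert rep.f1 == pytest.approx(0.8421, abs=1e-4)
        assert rep.mcc == pytest.approx(0.7035, abs=1e-4)

    def test_matches_hand_oracle_on_random_matrices(self, rng):
        for _ in range(100):
            tp, fp, fn, tn = rng.integers(0, 50, size=4)
            if tp + fp + fn + tn == 0:
                continue
            cm = ConfusionMatrix.from_binary_cells(int(tp), int(fp),
                                                   int(fn), int(tn))
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = metric_suite(cm)
            expected = hand_metric_oracle(tp, fp, fn, tn)
            got = (rep.accuracy, rep.precision, rep.recall, rep.specificity,
                   rep.f1, rep.mcc)
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_agrees_with_sklearn_cross_check(self, rng):
        from sklearn.metrics import f1_score, matthews_corrcoef

        y_true = rng.integers(0, 2, 200)
        y_pred = rng.integers(0, 2, 200)
        cm = confusion(y_true, y_pred, classes=[0, 1])
        rep = metric_suite(cm)
        assert rep.f1 == pytest.approx(f1_score(y_true, y_pred), abs=1e-12)
        assert rep.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred),
                                        abs=1e-12)

    def test_multiclass_weighted_recall_equals_accuracy(self, rng):
        y_true = rng.integers(0, 3, 300)
        y_pred = rng.integers(0, 3, 300)
        cm = confusion(y_true, y_pred, classes=[0, 1, 2])
        rep = metric_suite(cm, averaging="weighted")
        assert rep.recall == pytest.approx(rep.accuracy, abs=1e-12)

    def test_multiclass_mcc_matches_sklearn(self, rng):
        from sklearn.metrics import matthews_corrcoef

        y_true = rng.integers(0, 3, 300)
        y_pred = rng.integers(0, 3, 300)
        cm = confusion(y_true, y_pred, classes=[0, 1, 2])
        rep = metric_suite(cm, averaging="weighted")
        assert rep.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred),
                                        abs=1e-12)

    def test_mcc_invariant_under_class_swap_but_f1_not(self):
        cm = ConfusionMatrix.from_binary_cells(tp=40, fp=10, fn=5, tn=45)
        swapped = ConfusionMatrix.from_binary_cells(tp=45, fp=5, fn=10, tn=40)
        a, b = metric_suite(cm), metric_suite(swapped)
        assert a.mcc == pytest.approx(b.mcc, abs=1e-12)
        assert a.f1 != pytest.approx(b.f1, abs=1e-6)

    def test_zero_denominator_warns_and_reports_zero(self):
        cm = ConfusionMatrix.from_binary_cells(tp=0, fp=0, fn=5, tn=5)
        with pytest.warns(UserWarning, match="zero denominator"):
            rep = metric_suite(cm)
        assert rep.precision == 0.0 and rep.f1 == 0.0


class TestCVProtocol:
    def _feature_data(self, n_participants=40, windows=3, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.array([0, 1] * (n_participants // 2))
        rows, y, pids = [], [], []
        for i, lab in enumerate(labels):
            centre = lab * 1.5
            for _ in range(windows):
                rows.append(rng.normal(centre, 1.0, 4))
                y.append(lab)
                pids.append(f"p{i:02d}")
        return (pd.DataFrame(rows, columns=list("abcd")), np.array(y),
                np.array(pids))

    def test_three_by_ten_yields_thirty_paired_scores(self):
        frame, y, pids = self._feature_data()
        res = repeated_stratified_cv(["logistic", "random_forest"], frame, y,
                                     pids, repeats=3, k=10, seed=0,
                                     hyperparams={"random_forest":
                                                  {"n_estimators": 30}})
        assert all(len(r.fold_scores) == 30 for r in res.values())

    def test_folds_identical_across_models_and_seed_stable(self):
        frame, y, pids = self._feature_data(seed=1)
        a = participant_folds(pids, y, repeats=2, k=5, seed=9)
        b = participant_folds(pids, y, repeats=2, k=5, seed=9)
        assert len(a) == 10
        for (tr1, te1), (tr2, te2) in zip(a, b):
            np.testing.assert_array_equal(tr1, tr2)
            np.testing.assert_array_equal(te1, te2)

    def test_no_participant_straddles_folds(self):
        frame, y, pids = self._feature_data(seed=2)
        for tr, te in participant_folds(pids, y, repeats=1, k=5, seed=0):
            assert not (set(pids[tr]) & set(pids[te]))

    def test_fold_class_proportions_close_to_global(self):
        frame, y, pids = self._feature_data(seed=3)
        global_rate = y.mean()
        for _, te in participant_folds(pids, y, repeats=1, k=5, seed=0):
            # one participant (= 3 windows) of slack at this cohort size
            assert abs(y[te].mean() - global_rate) <= 3 / len(te)

    def test_class_smaller_than_k_rejected(self):
        frame, y, pids = self._feature_data(n_participants=10)
        with pytest.raises(ValueError, match="fewer than k"):
            participant_folds(pids, y, repeats=1, k=10, seed=0)


class TestPairedT:
    def test_identical_scores_give_p_one(self):
        t, p = paired_t_test([0.8, 0.9, 0.7], [0.8, 0.9, 0.7])
        assert t == 0.0 and p == 1.0

    def test_closed_form_example(self):
        t, p = paired_t_test([0.9, 0.8, 0.7], [0.6, 0.7, 0.5])
        assert t == pytest.approx(3.4641, abs=1e-4)
        assert p == pytest.approx(0.0742, abs=1e-3)

    def test_swapping_negates_t_preserves_p(self):
        a, b = [0.9, 0.85, 0.7, 0.95], [0.6, 0.7, 0.5, 0.8]
        t1, p1 = paired_t_test(a, b)
        t2, p2 = paired_t_test(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_constant_nonzero_difference_warns(self):
        with pytest.warns(UserWarning, match="diverges"):
            t, p = paired_t_test([1.0, 2.0], [0.5, 1.5])
        assert p == 0.0 and np.isinf(t)

    def test_matches_scipy(self, rng):
        from scipy.stats import ttest_rel

        a, b = rng.normal(0.8, 0.05, 30), rng.normal(0.75, 0.05, 30)
        t, p = paired_t_test(a, b)
        ref = ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestHolm:
    def test_single_p_unchanged(self):
        adj, rej = holm_adjust([0.03])
        assert adj[0] == pytest.approx(0.03) and rej[0]

    def test_hand_step_down_example(self):
        adj, rej = holm_adjust([0.01, 0.02, 0.04], alpha=0.05)
        np.testing.assert_allclose(adj, [0.03, 0.04, 0.04])
        assert rej.all()

    def test_adjusted_dominate_raw_and_monotone(self, rng):
        p = rng.uniform(0, 1, 20)
        adj, _ = holm_adjust(p)
        assert np.all(adj >= p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_rejects_superset_of_bonferroni(self, rng):
        for _ in range(100):
            m = rng.integers(2, 10)
            p = rng.uniform(0, 0.2, m)
            _, holm_rej = holm_adjust(p, alpha=0.05)
            bonf_rej = p <= 0.05 / m
            assert np.all(holm_rej[bonf_rej])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 0.3, 8)
        adj, rej = holm_adjust(p, alpha=0.05)
        ref_rej, ref_adj, *_ = multipletests(p, alpha=0.05, method="holm")
        np.testing.assert_allclose(adj, ref_adj, atol=1e-12)
        np.testing.assert_array_equal(rej, ref_rej)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


def test_significance_protocol_orders_and_flags(rng):
    from actidep.model_eval import CVResult

    base = rng.normal(0.9, 0.02, 30)
    results = {
        "gradient_boosting": CVResult("gradient_boosting", base, None),
        "logistic": CVResult("logistic", base - 0.1 + rng.normal(0, 0.01, 30),
                             None),
        "svm": CVResult("svm", base + rng.normal(0, 0.005, 30), None),
    }
    report = significance_protocol(results, baseline="gradient_boosting")
    rows = report.to_records()
    assert [r["rival"] for r in rows][0] == "logistic"
    by_rival = {r["rival"]: r for r in rows}
    assert by_rival["logistic"]["reject"]
    assert not by_rival["svm"]["reject"]
    assert all(r["p_holm"] >= r["p_raw"] for r in rows)
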