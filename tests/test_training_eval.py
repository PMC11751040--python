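import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cyspred as cp
from cyspred.training_eval import evaluate_scores, fit_baseline, baseline_scores


def mcc_bruteforce(tp, fn, tn, fp):
    denom = (tp + fn) * (tn + fn) * (tp + fp) * (tn + fp)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def auroc_pair_counting(scores, labels):
    """Concordant-pair fraction with half credit for ties."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        sn, sp, acc, mcc, flags = cp.confusion_metrics(50, 0, 50, 0)
        assert (sn, sp, acc, mcc) == (1.0, 1.0, 1.0, 1.0)
        assert flags == ()

    def test_always_wrong_classifier(self):
        sn, sp, acc, mcc, flags = cp.confusion_metrics(0, 50, 0, 50)
        assert (sn, sp, acc) == (0.0, 0.0, 0.0)
        # every denominator factor is 50, so MCC is well-defined and -1
        assert mcc == -1.0 and flags == ()

    def test_degenerate_single_column_confusion(self):
        sn, sp, acc, mcc, flags = cp.confusion_metrics(0, 0, 40, 10)
        assert mcc == 0.0 and "mcc" in flags and "sn" in flags

    def test_worked_example(self):
        sn, sp, acc, mcc, _ = cp.confusion_metrics(40, 10, 35, 15)
        assert sn == pytest.approx(0.8)
        assert sp == pytest.approx(0.7)
        assert acc == pytest.approx(0.75)
        assert mcc == pytest.approx(0.5025, abs=1e-4)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            cp.confusion_metrics(0, 0, 0, 0)

    @given(st.tuples(*[st.integers(0, 200)] * 4))
    @settings(deadline=None, max_examples=200)
    def test_agrees_with_direct_formulas(self, counts):
        tp, fn, tn, fp = counts
        if tp + fn + tn + fp == 0:
            return
        sn, sp, acc, mcc, _ = cp.confusion_metrics(tp, fn, tn, fp)
        assert mcc == pytest.approx(mcc_bruteforce(tp, fn, tn, fp), abs=1e-12)
        if tp + fn:
            assert sn == pytest.approx(tp / (tp + fn))
        if tn + fp:
            assert sp == pytest.approx(tn / (tn + fp))
        assert acc == pytest.approx((tp + tn) / (tp + fn + tn + fp))

    @given(st.tuples(*[st.integers(0, 100)] * 4))
    @settings(deadline=None, max_examples=100)
    def test_mcc_invariant_under_class_swap(self, counts):
        tp, fn, tn, fp = counts
        if tp + fn + tn + fp == 0:
            return
        _, _, _, a, _ = cp.confusion_metrics(tp, fn, tn, fp)
        _, _, _, b, _ = cp.confusion_metrics(tn, fp, tp, fn)
        assert a == pytest.approx(b, abs=1e-12)


class TestRocPr:
    def test_perfect_separation(self):
        auroc, aupr = cp.roc_pr_curves([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auroc == 1.0 and aupr == 1.0

    def test_constant_scores_give_half_auroc(self):
        auroc, _ = cp.roc_pr_curves([0.5] * 10, [1, 0] * 5)
        assert auroc == pytest.approx(0.5)

    def test_worked_example(self):
        auroc, _ = cp.roc_pr_curves([0.9, 0.8, 0.4, 0.2], [1, 0, 1, 0])
        assert auroc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            cp.roc_pr_curves([0.1, 0.2], [1, 1])

    def test_agrees_with_pair_counting(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(4, 40)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.random(n), 2)  # rounding induces ties
            auroc, _ = cp.roc_pr_curves(scores, labels)
            assert auroc == pytest.approx(auroc_pair_counting(scores, labels),
                                          abs=1e-12)


class TestTrain:
    def spec(self, **kw):
        defaults = dict(epochs=5, batch_size=8, learning_rate=1e-2, seed=0,
                        early_stopping_patience=None)
        defaults.update(kw)
        return cp.TrainSpec(**defaults)

    def test_same_seed_reproduces_parameters(self, separable_dataset,
                                             tiny_model_config):
        weights = []
        for _ in range(2):
            model = cp.build_model(tiny_model_config, L=11, feature_dim=20, seed=1)
            cp.train(model, separable_dataset, cp.EncodingConfig(L=11), self.spec())
            weights.append(model.get_weights())
        for k in weights[0]:
            assert np.array_equal(weights[0][k], weights[1][k])

    def test_separable_toy_reaches_full_accuracy(self, separable_dataset):
        cfg = cp.ModelConfig(conv_channels=(4, 6), kernel_sizes=(3, 3), pool_size=2,
                             lstm_hidden=6, attention_dim=5, fc_sizes=(8, 6),
                             dropout=0.0)
        model = cp.build_model(cfg, L=11, feature_dim=20, seed=0)
        _, history = cp.train(model, separable_dataset, cp.EncodingConfig(L=11),
                              self.spec(epochs=200, learning_rate=3e-3))
        report = cp.evaluate(model, separable_dataset, cp.EncodingConfig(L=11))
        assert report.acc == 1.0
        # loss trends down on a separable problem
        assert history["train_loss"][-1] < history["train_loss"][0] / 5

    def test_history_length_without_early_stop(self, separable_dataset,
                                               tiny_model_config):
        model = cp.build_model(tiny_model_config, L=11, feature_dim=20, seed=0)
        _, history = cp.train(model, separable_dataset, cp.EncodingConfig(L=11),
                              self.spec(epochs=7))
        assert len(history["train_loss"]) == 7
        assert "val_loss" not in history

    def test_early_stopping_restores_best(self, separable_dataset,
                                          tiny_model_config):
        model = cp.build_model(tiny_model_config, L=11, feature_dim=20, seed=0)
        _, history = cp.train(
            model, separable_dataset, cp.EncodingConfig(L=11),
            self.spec(epochs=50, early_stopping_patience=3),
        )
        assert len(history["val_loss"]) <= 50

    def test_single_class_rejected(self, tiny_model_config):
        ds = cp.LabeledDataset([
            cp.PeptideWindow("AAAAACAAAAA", "p", 6, label=1) for _ in range(4)
        ])
        model = cp.build_model(tiny_model_config, L=11, feature_dim=20, seed=0)
        with pytest.raises(ValueError, match="both classes"):
            cp.train(model, ds, cp.EncodingConfig(L=11), self.spec())


class TestCrossValidate:
    def test_every_window_evaluated_once_per_repeat(self, separable_dataset,
                                                    tiny_model_config):
        spec = cp.TrainSpec(epochs=2, batch_size=8, seed=0,
                            early_stopping_patience=None)
        summary, rows = cp.cross_validate(
            separable_dataset, tiny_model_config, cp.EncodingConfig(L=11),
            spec, k=2, repeats=2, collect_predictions=True,
        )
        assert len(summary.reports) == 4
        for r in range(2):
            indices = sorted(row[0] for row in rows if row[1] == r)
            assert indices == list(range(len(separable_dataset)))

    def test_rerun_reproduces_summary(self, separable_dataset, tiny_model_config):
        spec = cp.TrainSpec(epochs=2, batch_size=8, seed=3,
                            early_stopping_patience=None)
        a = cp.cross_validate(separable_dataset, tiny_model_config,
                              cp.EncodingConfig(L=11), spec, k=2, repeats=1)
        b = cp.cross_validate(separable_dataset, tiny_model_config,
                              cp.EncodingConfig(L=11), spec, k=2, repeats=1)
        assert a.mean == b.mean and a.sd == b.sd

    def test_summary_statistics_are_population_sd(self):
        reports = [
            evaluate_scores([0.9, 0.1], [1, 0]),
            evaluate_scores([0.6, 0.8], [1, 0]),
        ]
        summary = cp.CVSummary(reports=reports, n_folds=2, n_repeats=1)
        accs = [r.acc for r in reports]
        assert summary.mean["acc"] == pytest.approx(np.mean(accs))
        assert summary.sd["acc"] == pytest.approx(np.std(accs))


class TestMannWhitney:
    def test_identical_samples_not_significant(self):
        u, p, tier = cp.mann_whitney_compare([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == 1.0 and tier == "NS"

    def test_fully_separated_samples(self):
        u, p, tier = cp.mann_whitney_compare([1, 2, 3], [4, 5, 6])
        assert u == 0.0  # no pair with a > b
        # exact two-sided p for complete separation at n=m=3 is 0.1
        assert p == pytest.approx(0.1)
        assert tier == "NS"

    def test_swap_symmetry(self):
        a, b = [1.0, 2.5, 3.0, 4.5], [2.0, 3.5, 5.0]
        ua, pa, _ = cp.mann_whitney_compare(a, b)
        ub, pb, _ = cp.mann_whitney_compare(b, a)
        assert ua + ub == len(a) * len(b)
        assert pa == pytest.approx(pb)

    def test_u_matches_enumeration(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=6), rng.normal(size=5)
        u, _, _ = cp.mann_whitney_compare(a, b)
        u_ref = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
        assert u == pytest.approx(u_ref)

    def test_strong_difference_is_significant(self):
        a = list(range(10))
        b = [x + 100 for x in range(10)]
        _, p, tier = cp.mann_whitney_compare(a, b)
        assert p < 0.001 and tier == "***"

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            cp.mann_whitney_compare([1, 2], [3, 4, 5])


class TestBaselines:
    @pytest.mark.parametrize("name", ["rf", "xgboost"])
    def test_baseline_learns_separable_toy(self, separable_dataset, name):
        clf = fit_baseline(name, separable_dataset, cp.EncodingConfig(L=11), seed=0)
        scores = baseline_scores(clf, separable_dataset, cp.EncodingConfig(L=11))
        auroc, _ = cp.roc_pr_curves(scores, separable_dataset.labels)
        assert auroc > 0.95

    def test_unknown_baseline_rejected(self, separable_dataset):
        with pytest.raises(ValueError, match="unknown baseline"):
            fit_baseline("mlp", separable_dataset)
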