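import numpy as np
import pytest

from emaclass.classify import (
    LabeledDataset,
    StratificationError,
    TrainConfig,
    TrainedModel,
    adaboost_stage_weight,
    decision_scores,
    predict,
    split_repeated,
    train_adaboost,
    train_svm_ecoc,
    undersample,
)
from emaclass.metrics import CLASSES

SMALL_SVM = dict(svm_C_grid=(1.0, 10.0), svm_gamma_grid=(0.01, 0.1))


def gaussian_clouds(n_per_class, separation, dim=5, seed=0, classes=("I", "II")):
    """Well-separated (or not) Gaussian feature clouds as a LabeledDataset."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for i, c in enumerate(classes):
        center = np.zeros(dim)
        center[i % dim] = separation * i
        X.append(rng.normal(center, 1.0, (n_per_class, dim)))
        y += [c] * n_per_class
    return LabeledDataset(np.vstack(X), np.array(y, dtype=object))


class TestSplitRepeated:
    def test_balanced_counts_split_seven_three(self):
        ds = gaussian_clouds(10, 1.0, classes=CLASSES)
        cfg = TrainConfig(seed=1, n_repeats=3)
        for tr, te in split_repeated(ds, cfg):
            for c in CLASSES:
                assert np.sum(ds.labels[tr] == c) == 7
                assert np.sum(ds.labels[te] == c) == 3

    def test_clinical_profile_counts_round_half_up(self):
        # per-class train sizes for counts (274, 2260, 13, 50) at 70%
        rng = np.random.default_rng(0)
        labels = np.repeat(list(CLASSES), [274, 2260, 13, 50])
        X = rng.normal(size=(len(labels), 3))
        ds = LabeledDataset(X, labels.astype(object))
        tr, te = split_repeated(ds, TrainConfig(seed=0, n_repeats=1))[0]
        got = [int(np.sum(ds.labels[tr] == c)) for c in CLASSES]
        assert got == [192, 1582, 9, 35]

    def test_disjoint_exhaustive_and_deterministic(self):
        ds = gaussian_clouds(9, 1.0, classes=CLASSES)
        cfg = TrainConfig(seed=42, n_repeats=4)
        s1 = split_repeated(ds, cfg)
        s2 = split_repeated(ds, cfg)
        for (tr1, te1), (tr2, te2) in zip(s1, s2):
            assert np.array_equal(tr1, tr2) and np.array_equal(te1, te2)
            assert len(np.intersect1d(tr1, te1)) == 0
            assert len(np.union1d(tr1, te1)) == len(ds)

    def test_class_below_two_samples_errors_naming_class(self):
        labels = np.array(["I"] * 5 + ["II"] * 5 + ["III"], dtype=object)
        ds = LabeledDataset(np.zeros((11, 2)), labels)
        with pytest.raises(StratificationError, match="III"):
            split_repeated(ds, TrainConfig())


class TestSvmEcoc:
    def test_separable_clouds_reach_perfect_training_accuracy(self):
        ds = gaussian_clouds(50, 10.0, seed=1)
        cfg = TrainConfig(seed=0, **SMALL_SVM)
        model = train_svm_ecoc(ds, cfg)
        pred, _ = predict(model, ds.features)
        assert np.mean(pred == ds.labels) == 1.0

    def test_single_class_training_set_rejected(self):
        ds = LabeledDataset(np.random.default_rng(0).normal(size=(10, 3)),
                            np.array(["II"] * 10, dtype=object))
        with pytest.raises(ValueError, match="degenerate"):
            train_svm_ecoc(ds, TrainConfig())

    def test_duplicated_rows_predict_their_label(self):
        rng = np.random.default_rng(3)
        x0 = rng.normal(size=3)
        X = np.vstack([np.tile(x0, (10, 1)), rng.normal(5.0, 1.0, (10, 3))])
        y = np.array(["I"] * 10 + ["II"] * 10, dtype=object)
        model = train_svm_ecoc(LabeledDataset(X, y), TrainConfig(seed=0, **SMALL_SVM))
        pred, _ = predict(model, x0[None, :])
        assert pred[0] == "I"

    def test_feature_length_mismatch_is_contract_error(self):
        ds = gaussian_clouds(20, 5.0)
        model = train_svm_ecoc(ds, TrainConfig(seed=0, **SMALL_SVM))
        with pytest.raises(ValueError, match="feature length"):
            predict(model, np.zeros((1, 7)))


class TestAdaBoost:
    def test_chance_level_weak_learner_gets_zero_weight(self):
        assert adaboost_stage_weight(0.5, n_classes=2) == pytest.approx(0.0)

    def test_stage_weight_decreases_with_error(self):
        assert adaboost_stage_weight(0.1) > adaboost_stage_weight(0.3) > 0

    def test_separable_data_reaches_zero_training_error(self):
        ds = gaussian_clouds(30, 8.0, seed=2)
        model = train_adaboost(ds, TrainConfig(seed=0, boost_cycles=20))
        pred, _ = predict(model, ds.features)
        assert np.mean(pred == ds.labels) == 1.0

    def test_single_cycle_equals_one_tree(self):
        from sklearn.tree import DecisionTreeClassifier

        ds = gaussian_clouds(25, 2.0, seed=4, classes=CLASSES)
        cfg = TrainConfig(seed=0, boost_cycles=1, tree_max_depth=3)
        model = train_adaboost(ds, cfg)
        pred, _ = predict(model, ds.features)
        Xs = (ds.features - model.scaler_mean) / model.scaler_scale
        tree = DecisionTreeClassifier(max_depth=3, random_state=cfg.seed + 2)
        tree.fit(Xs, ds.labels.astype(str))
        assert np.array_equal(pred.astype(str), tree.predict(Xs))


class StubScorer:
    def __init__(self, value):
        self.value = value

    def decision_function(self, X):
        return np.full(len(X), self.value)


def stub_model(scores):
    return TrainedModel(
        method="svm_ecoc",
        class_order=CLASSES,
        scaler_mean=np.zeros(2),
        scaler_scale=np.ones(2),
        feature_config_digest="stub",
        svm_scorers={c: {"svc": StubScorer(v)} for c, v in zip(CLASSES, scores)},
    )


class TestPredict:
    def test_argmax_selects_highest_score(self):
        model = stub_model((0.9, 0.1, 0.1, 0.1))
        pred, scores = predict(model, np.zeros((1, 2)))
        assert pred[0] == "I"
        assert scores.shape == (1, 4)

    def test_exact_tie_goes_to_earlier_class(self):
        model = stub_model((0.0, 0.7, 0.1, 0.7))
        pred, _ = predict(model, np.zeros((1, 2)))
        assert pred[0] == "II"


class TestUndersample:
    def _dataset(self, counts, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.repeat(list(CLASSES), counts)
        return LabeledDataset(rng.normal(size=(len(labels), 2)), labels.astype(object))

    def test_clinical_profile_counts(self):
        ds = self._dataset([274, 2260, 13, 50])
        out = undersample(ds, seed=0)
        assert [out.class_counts[c] for c in CLASSES] == [274, 274, 13, 50]

    def test_already_balanced_unchanged(self):
        ds = self._dataset([10, 10, 3, 2])
        out = undersample(ds, seed=0)
        assert np.array_equal(out.features, ds.features)
        assert np.array_equal(out.labels, ds.labels)

    def test_deterministic_and_without_replacement(self):
        ds = self._dataset([20, 100, 5, 5])
        a = undersample(ds, seed=7)
        b = undersample(ds, seed=7)
        assert np.array_equal(a.features, b.features)
        # no duplicated surviving rows
        assert len(np.unique(a.features, axis=0)) == len(a.features)

    def test_minority_classes_untouched_and_order_preserved(self):
        ds = self._dataset([20, 100, 5, 5])
        out = undersample(ds, seed=1)
        for c in ("I", "III", "IV"):
            assert np.array_equal(
                out.features[out.labels == c], ds.features[ds.labels == c]
            )
        # survivors keep original relative order: each surviving row appears
        # in the same sequence as in the source
        src_rows = [tuple(r) for r in ds.features]
        out_rows = [tuple(r) for r in out.features]
        it = iter(src_rows)
        assert all(any(row == s for s in it) for row in out_rows)

    def test_negative_below_positive_rejected(self):
        ds = self._dataset([30, 10, 2, 2])
        with pytest.raises(ValueError, match="under-sample"):
            undersample(ds, seed=0)


class TestProtocolProperties:
    def test_end_to_end_determinism(self):
        ds = gaussian_clouds(15, 2.0, seed=5, classes=CLASSES)
        cfg = TrainConfig(seed=9, n_repeats=2, **SMALL_SVM)
        outs = []
        for _ in range(2):
            preds = []
            for tr, te in split_repeated(ds, cfg):
                model = train_svm_ecoc(ds.subset(tr), cfg)
                p, s = predict(model, ds.features[te])
                preds.append((p.astype(str), s))
            outs.append(preds)
        for (p1, s1), (p2, s2) in zip(*outs):
            assert np.array_equal(p1, p2)
            assert np.array_equal(s1, s2)

    def test_accuracy_monotone_in_separation(self):
        # held-out accuracy should not degrade as clusters separate (within
        # Monte-Carlo tolerance over 5 seeds)
        seps = [0.0, 1.0, 2.0, 4.0]
        mean_acc = []
        for sep in seps:
            accs = []
            for seed in range(5):
                ds = gaussian_clouds(20, sep, seed=seed)
                cfg = TrainConfig(seed=seed, n_repeats=1, **SMALL_SVM)
                tr, te = split_repeated(ds, cfg)[0]
                model = train_svm_ecoc(ds.subset(tr), cfg)
                p, _ = predict(model, ds.features[te])
                accs.append(np.mean(p == ds.labels[te]))
            mean_acc.append(np.mean(accs))
        for lo, hi in zip(mean_acc, mean_acc[1:]):
            assert hi >= lo - 0.08  # Monte-Carlo slack
        assert mean_acc[-1] > mean_acc[0]

    def test_label_permutation_gives_chance_accuracy(self):
        rng = np.random.default_rng(11)
        ds = gaussian_clouds(30, 6.0, seed=6)
        shuffled = LabeledDataset(ds.features, rng.permutation(ds.labels))
        cfg = TrainConfig(seed=0, n_repeats=3, **SMALL_SVM)
        accs, majority = [], []
        for tr, te in split_repeated(shuffled, cfg):
            model = train_svm_ecoc(shuffled.subset(tr), cfg)
            p, _ = predict(model, shuffled.features[te])
            accs.append(np.mean(p == shuffled.labels[te]))
            counts = [np.sum(shuffled.labels[te] == c) for c in ("I", "II")]
            majority.append(max(counts) / len(te))
        n = len(shuffled.labels)  # distinct samples, not pooled predictions
        se = np.sqrt(0.5 * 0.5 / n)
        assert abs(np.mean(accs) - np.mean(majority)) <= 3 * se + 0.05
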