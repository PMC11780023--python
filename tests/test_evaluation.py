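import numpy as np
import pandas as pd
import pytest

from dlradiomics.evaluation import (
    EvalReport,
    ModelSpec,
    compare_models,
    evaluate,
    stratified_split,
    train_model,
)


class FixedScores:
    """Minimal probability-scoring stand-in for a fitted classifier."""

    def __init__(self, prob, classes=(0, 1, 2)):
        self.prob = np.asarray(prob, dtype=float)
        self.classes_ = np.asarray(classes)

    def predict_proba(self, X):
        return self.prob[: len(X)]


def blobs(n_per_class=20, sep=8.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.concatenate(
        [rng.normal(loc=c * sep, scale=1.0, size=(n_per_class, 4)) for c in range(3)]
    )
    y = np.repeat([0, 1, 2], n_per_class)
    return pd.DataFrame(X, columns=list("abcd")), y


class TestStratifiedSplit:
    def test_306_to_244_62(self):
        labels = np.repeat([0, 1, 2], [108, 102, 96])
        ids = [f"c{i}" for i in range(306)]
        split = stratified_split(ids, labels, seed=0)
        assert len(split.ids("train")) == 244
        assert len(split.ids("internal_test")) == 62

    def test_two_class_quota(self):
        labels = np.repeat([0, 1], [5, 5])
        ids = [f"c{i}" for i in range(10)]
        split = stratified_split(ids, labels, seed=1)
        test = split.ids("internal_test")
        assert len(test) == 2
        test_labels = [labels[int(c[1:])] for c in test]
        assert sorted(test_labels) == [0, 1]

    def test_deterministic(self):
        labels = np.repeat([0, 1, 2], [8, 9, 10])
        ids = [f"c{i}" for i in range(27)]
        a = stratified_split(ids, labels, seed=5)
        b = stratified_split(ids, labels, seed=5)
        assert a.assignment == b.assignment

    def test_external_never_in_train(self):
        labels = np.repeat([0, 1, 2], 10)
        ids = [f"c{i}" for i in range(30)]
        tags = ["external" if i % 3 == 0 else "train_pool" for i in range(30)]
        split = stratified_split(ids, labels, tags, seed=0)
        for cid in split.ids("external_test"):
            assert tags[int(cid[1:])] == "external"
        assert len(split.ids("external_test")) == 10

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            stratified_split(["a", "b", "c"], [0, 0, 1])


class TestTrainModel:
    @pytest.mark.parametrize("clf", ["svm", "rf"])
    def test_separable_blobs_train_accuracy(self, clf):
        X, y = blobs()
        spec = ModelSpec(modality="radiomics", phase="AP", classifier=clf)
        model = train_model(spec, X, y)
        assert (model.predict(X.to_numpy()) == y).mean() == 1.0

    def test_deterministic(self):
        X, y = blobs(sep=2.0, seed=3)
        spec = ModelSpec(modality="radiomics", phase="AP", classifier="rf")
        a = train_model(spec, X, y).predict_proba(X.to_numpy())
        b = train_model(spec, X, y).predict_proba(X.to_numpy())
        assert np.array_equal(a, b)

    def test_unknown_classifier(self):
        with pytest.raises(ValueError, match="xgb"):
            ModelSpec(modality="radiomics", phase="AP", classifier="xgb")


class TestEvaluate:
    def test_perfect_scores(self):
        y = np.repeat([0, 1, 2], 4)
        prob = np.zeros((12, 3))
        prob[np.arange(12), y] = 1.0
        rep = evaluate(FixedScores(prob), pd.DataFrame(np.zeros((12, 1))), y,
                       n_bootstrap=50, seed=0)
        assert rep.accuracy == 1.0
        assert rep.macro_auc == 1.0
        assert rep.f1_macro == 1.0
        assert np.array_equal(rep.confusion, np.diag([4, 4, 4]))

    def test_label_independent_scores_near_chance(self):
        rng = np.random.default_rng(0)
        n = 600
        y = np.repeat([0, 1, 2], n // 3)
        prob = rng.dirichlet(np.ones(3), size=n)
        rep = evaluate(FixedScores(prob), pd.DataFrame(np.zeros((n, 1))), y,
                       n_bootstrap=10, seed=0)
        assert 0.45 <= rep.macro_auc <= 0.55

    def test_binary_reduction_matches_two_class_auc(self):
        rng = np.random.default_rng(1)
        n = 100
        y = np.repeat([0, 1], n // 2)
        score1 = np.clip(y + rng.normal(0, 0.8, n), -2, 3)
        prob = np.column_stack([1 - _sigmoid(score1), _sigmoid(score1), np.zeros(n)])
        with pytest.warns(UserWarning, match="absent"):
            rep = evaluate(FixedScores(prob), pd.DataFrame(np.zeros((n, 1))), y,
                           n_bootstrap=10, seed=0)
        from sklearn.metrics import roc_auc_score

        direct = roc_auc_score(y, _sigmoid(score1))
        # class-0 OvR AUC equals the class-1 AUC by symmetry; macro = both
        assert np.isclose(rep.macro_auc, direct, atol=1e-12)

    def test_micro_equals_macro_on_balanced_calibrated_toy(self):
        y = np.repeat([0, 1, 2], 10)
        prob = np.full((30, 3), 0.2)
        prob[np.arange(30), y] = 0.6
        rep = evaluate(FixedScores(prob), pd.DataFrame(np.zeros((30, 1))), y,
                       n_bootstrap=10, seed=0)
        assert np.isclose(rep.macro_auc, rep.micro_auc)
        assert rep.macro_auc == 1.0

    def test_absent_class_warns_and_averages_present(self):
        y = np.repeat([0, 1], 6)
        prob = np.full((12, 3), 1 / 3)
        with pytest.warns(UserWarning, match="absent"):
            rep = evaluate(FixedScores(prob), pd.DataFrame(np.zeros((12, 1))), y,
                           n_bootstrap=10, seed=0)
        assert set(rep.per_class_auc) == {0, 1}

    def test_ci_width_shrinks_with_n(self):
        rng = np.random.default_rng(2)
        widths = []
        for n in (99, 399):
            y = np.repeat([0, 1, 2], n // 3)
            score = rng.normal(0, 1, (n, 3))
            score[np.arange(n), y] += 1.5
            e = np.exp(score)
            prob = e / e.sum(1, keepdims=True)
            rep = evaluate(FixedScores(prob), pd.DataFrame(np.zeros((n, 1))), y,
                           n_bootstrap=400, seed=0)
            widths.append(rep.ci_95[1] - rep.ci_95[0])
        assert widths[1] < widths[0]

    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(3)
        n = 90
        y = np.repeat([0, 1, 2], n // 3)
        score = rng.normal(0, 1, (n, 3))
        score[np.arange(n), y] += 1.0
        e = np.exp(score)
        rep = evaluate(FixedScores(e / e.sum(1, keepdims=True)),
                       pd.DataFrame(np.zeros((n, 1))), y, n_bootstrap=500, seed=1)
        assert rep.ci_95[0] - 0.02 <= rep.macro_auc <= rep.ci_95[1] + 0.02


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _report(name, auc, acc, f1, split="internal_test"):
    return EvalReport(
        model_name=name, split_name=split, n=10,
        confusion=np.diag([3, 3, 4]), accuracy=acc,
        precision_macro=f1, recall_macro=f1, f1_macro=f1,
        per_class_auc={0: auc, 1: auc, 2: auc}, macro_auc=auc, micro_auc=auc,
        ci_95=(auc - 0.05, min(1.0, auc + 0.05)), n_bootstrap=10,
    )


class TestCompareModels:
    def test_sorted_by_macro_auc(self):
        table = compare_models([_report("a", 0.9, 0.8, 0.8), _report("b", 0.95, 0.7, 0.7)])
        assert table["model"].tolist() == ["b", "a"]

    def test_tie_broken_by_accuracy(self):
        table = compare_models([_report("a", 0.9, 0.80, 0.8), _report("b", 0.9, 0.85, 0.8)])
        assert table["model"].tolist() == ["b", "a"]

    def test_singleton(self):
        assert len(compare_models([_report("only", 0.9, 0.9, 0.9)])) == 1

    def test_split_mismatch_rejected(self):
        with pytest.raises(ValueError, match="different splits"):
            compare_models([_report("a", 0.9, 0.9, 0.9),
                            _report("b", 0.9, 0.9, 0.9, split="external_test")])
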