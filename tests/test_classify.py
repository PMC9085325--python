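"""Classifiers, ROC/AUC, ternary voting and the CV harness."""

import dataclasses

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from imgram.classify import (
    ClassifierConfig,
    FittedPipeline,
    cross_validate,
    decision_scores,
    images_to_docs,
    predict_ternary,
    roc_auc,
    roc_points,
    train_binary,
)
from imgram.config import PipelineConfig
from imgram.synthetic_data import make_dataset, two_class_specs


class TestRocAuc:
    def test_closed_forms(self):
        assert roc_auc([0.9, 0.8, 0.3, 0.1], [1, 1, 0, 0]) == 1.0
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0]) == 0.0
        # 4 positive-negative pairs, 3 correctly ordered -> 0.75
        assert roc_auc([0.9, 0.8, 0.3, 0.1], [1, 0, 1, 0]) == 0.75

    def test_ties_contribute_half(self):
        assert roc_auc([0.5, 0.5], [1, 0]) == 0.5

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(10, 60)
            scores = np.round(rng.normal(size=n), 1)  # rounding induces ties
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            assert roc_auc(scores, y) == pytest.approx(roc_auc_score(y, scores))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_roc_points_start_and_end(self):
        fpr, tpr = roc_points([0.9, 0.8, 0.3, 0.1], [1, 0, 1, 0])
        assert fpr[0] == tpr[0] == 0.0
        assert fpr[-1] == tpr[-1] == 1.0
        assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()


class TestTrainBinary:
    def test_svm_separable_training_accuracy(self):
        X = np.vstack([np.random.default_rng(1).normal(0, 0.1, (10, 2)) + [0, 0],
                       np.random.default_rng(2).normal(0, 0.1, (10, 2)) + [5, 5]])
        y = np.array([0] * 10 + [1] * 10)
        model = train_binary(X, y, ClassifierConfig(kind="svm"))
        assert (model.predict(X) == y).all()
        assert decision_scores(model, X).shape == (20,)

    def test_mlp_seeded_determinism(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 5))
        y = rng.integers(0, 2, 30)
        cfg = ClassifierConfig(kind="mlp", seed=123)
        s1 = decision_scores(train_binary(X, y, cfg), X)
        s2 = decision_scores(train_binary(X, y, cfg), X)
        np.testing.assert_array_equal(s1, s2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_binary(np.zeros((4, 2)), [1, 1, 1, 1], ClassifierConfig())

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ClassifierConfig(kind="forest")
        with pytest.raises(ValueError):
            ClassifierConfig(svm_c=-1)
        with pytest.raises(ValueError):
            ClassifierConfig(mlp_hidden=(3, 0))


class _StubModel:
    """Minimal pairwise-model stand-in for exercising the voting rule."""

    def __init__(self, positive_class, negative_class, scores):
        self.positive_class = positive_class
        self.negative_class = negative_class
        self._scores = np.asarray(scores, dtype=float)
        self.model = object()

    def decision_scores(self, docs):
        return self._scores


class TestPredictTernary:
    def _models(self, s12, s13, s23):
        return [
            _StubModel(1, 2, s12),
            _StubModel(1, 3, s13),
            _StubModel(2, 3, s23),
        ]

    def test_unanimity_and_majority(self):
        # all three favour class 2: (1,2)->2, (1,3) irrelevant, (2,3)->2
        models = self._models([-1.0], [-0.2], [0.8])
        assert predict_ternary(models, [None]) == [2]
        # votes (1, 1, 3) -> majority 1
        models = self._models([0.5], [0.9], [-0.1])
        assert predict_ternary(models, [None]) == [1]

    def test_three_way_tie_broken_by_largest_score(self):
        # votes (1, 3, 2): strongest subclassifier is (1,3) with |-2.0|
        models = self._models([0.3], [-2.0], [0.4])
        assert predict_ternary(models, [None]) == [3]

    def test_missing_model_rejected(self):
        with pytest.raises(ValueError):
            predict_ternary(self._models([0], [0], [0])[:2], [None])


class TestFittedPipeline:
    def test_training_state_independent_of_test_documents(self, binary_dataset):
        """No leakage: the fitted state depends only on the training split."""
        keep = list(range(20)) + list(range(50, 70))  # 20 per class
        docs = images_to_docs([binary_dataset.images[i] for i in keep])
        labels = [binary_dataset.labels[i] for i in keep]
        cfg = PipelineConfig(seed=0)
        p1 = FittedPipeline(cfg, "class_b", "class_a").fit(docs, labels)
        p2 = FittedPipeline(cfg, "class_b", "class_a").fit(docs, labels)
        assert p1.vocabulary.tokens == p2.vocabulary.tokens
        np.testing.assert_array_equal(p1.selection.p_values, p2.selection.p_values)
        np.testing.assert_array_equal(p1.selection.ece, p2.selection.ece)
        np.testing.assert_array_equal(p1.selection.selected, p2.selection.selected)
        # scoring arbitrary held-out documents does not mutate the state
        other = images_to_docs(list(binary_dataset.images[40:50]))
        p1.decision_scores(other)
        np.testing.assert_array_equal(p1.selection.selected, p2.selection.selected)

    def test_unseen_tokens_dropped_at_test_time(self, binary_dataset):
        docs = images_to_docs(list(binary_dataset.images))
        pipe = FittedPipeline(PipelineConfig(), "class_b", "class_a").fit(
            docs, list(binary_dataset.labels)
        )
        from imgram.ngram import TokenCounts

        alien = TokenCounts({"@@@": 5})
        X = pipe.transform([alien])
        assert X.shape == (1, len(pipe.selection.selected))


class TestCrossValidate:
    def test_null_labels_give_chance_level_auc(self):
        from imgram.synthetic_data import ClassSpec

        bg = frozenset(range(8))
        specs = [ClassSpec("a", bg, (10, 11), 0.0), ClassSpec("b", bg, (10, 11), 0.0)]
        ds = make_dataset(specs, 50, (32, 32), seed=21)
        rep = cross_validate(list(ds.images), list(ds.labels), PipelineConfig(seed=21))
        assert 0.3 <= rep.auc <= 0.7

    def test_reports_are_byte_identical_for_identical_seeds(self, binary_dataset):
        cfg = PipelineConfig(seed=5, n_folds=5)
        images, labels = list(binary_dataset.images), list(binary_dataset.labels)
        r1 = cross_validate(images, labels, cfg)
        r2 = cross_validate(images, labels, cfg)
        assert r1.to_json() == r2.to_json()

    def test_fold_count_validation(self, binary_dataset):
        images, labels = list(binary_dataset.images[:12]), list(binary_dataset.labels[:12])
        with pytest.raises(ValueError):
            cross_validate(images, labels, PipelineConfig(n_folds=10))

    def test_mlp_binary_runs_and_reports(self, binary_dataset):
        cfg = PipelineConfig(
            seed=2, n_folds=4, fraction=0.25,
            classifier=ClassifierConfig(kind="mlp", seed=2),
        )
        images = list(binary_dataset.images[:20]) + list(binary_dataset.images[50:70])
        labels = list(binary_dataset.labels[:20]) + list(binary_dataset.labels[50:70])
        rep = cross_validate(images, labels, cfg)
        assert 0.0 <= rep.auc <= 1.0
        assert rep.kind == "binary"
        assert len(rep.scores) == len(images)

    def test_ternary_protocol_reports_per_class_fractions(self):
        from imgram.synthetic_data import three_class_specs

        ds = make_dataset(three_class_specs(), 12, (32, 32), seed=9)
        cfg = PipelineConfig(seed=9, n_folds=4, weighting="tf_rf", fraction=0.25)
        rep = cross_validate(list(ds.images), list(ds.labels), cfg)
        assert rep.kind == "ternary"
        assert set(rep.per_class_correct) == {"class_a", "class_b", "class_c"}
        assert all(0.0 <= v <= 1.0 for v in rep.per_class_correct.values())
        # disjoint planted motifs make the task easy
        assert np.mean(list(rep.per_class_correct.values())) >= 0.9
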