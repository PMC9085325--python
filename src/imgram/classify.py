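"""Cross-validated classification over selected n-gram features.

Binary tasks use an RBF-kernel SVM (C = 10, gamma = 0.01) or a small
back-propagation network (hidden layers 3-6-3, <= 100 epochs, learning
rate 0.01) evaluated by pooled ROC/AUC over stratified k-fold
cross-validation.  Ternary tasks use a majority vote of three pairwise
binary subclassifiers, each with its own vocabulary, weighting and
feature selection, reporting per-class correct fractions.

Everything that depends on labels — vocabulary, RF weights, rank-sum
p-values, ECE scores, feature scaling, the classifier itself — is fit
inside each fold's training split only.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Any, Hashable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import preprocess
from .encode import quantize
from .ngram import TokenCounts, build_vocabulary, count_matrix
from .selection import SelectionResult, select_features
from .weighting import apply_tf_rf, rf_weights, tf


@dataclass(frozen=True)
class ClassifierConfig:
    """Hyperparameters of the two classifier families.

    ``svm_c``/``svm_gamma`` parameterize the RBF SVM; ``mlp_hidden``,
    ``epochs``, ``goal`` (loss-improvement tolerance for early stopping)
    and ``learning_rate`` the back-propagation network.  ``seed`` fixes
    the network's weight initialization.
    """

    kind: str = "svm"
    svm_c: float = 10.0
    svm_gamma: float = 0.01
    mlp_hidden: tuple[int, ...] = (3, 6, 3)
    epochs: int = 100
    goal: float = 1e-5
    learning_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "mlp_hidden", tuple(self.mlp_hidden))
        if self.kind not in ("svm", "mlp"):
            raise ValueError(f"classifier kind must be 'svm' or 'mlp', got {self.kind!r}")
        for name in ("svm_c", "svm_gamma", "epochs", "goal", "learning_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if any(h <= 0 for h in self.mlp_hidden):
            raise ValueError("mlp_hidden sizes must be > 0")


def make_estimator(config: ClassifierConfig):
    if config.kind == "svm":
        return SVC(kernel="rbf", C=config.svm_c, gamma=config.svm_gamma)
    return MLPClassifier(
        hidden_layer_sizes=config.mlp_hidden,
        max_iter=config.epochs,
        tol=config.goal,
        learning_rate_init=config.learning_rate,
        solver="adam",
        random_state=config.seed,
    )


def train_binary(X: np.ndarray, y: Sequence[int], config: ClassifierConfig):
    """Fit a binary classifier exposing a continuous decision score.

    ``y`` must be 0/1 with the positive class coded 1 and both classes
    present.
    """
    y = np.asarray(y)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("train_binary needs both classes present, coded 0/1")
    model = make_estimator(config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(np.asarray(X, dtype=np.float64), y)
    return model


def decision_scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous score per document, oriented so > 0 favours class 1."""
    X = np.asarray(X, dtype=np.float64)
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=np.float64)
    return np.asarray(model.predict_proba(X)[:, 1] - 0.5, dtype=np.float64)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) formulation.

    Equals the probability that a random positive outscores a random
    negative; tied scores contribute 1/2.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both classes present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def roc_points(scores: Sequence[float], labels: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """(fpr, tpr) points of the empirical ROC curve, from (0,0) to (1,1)."""
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(bool)
    order = np.argsort(-scores, kind="mergesort")
    ys = y[order]
    tp = np.cumsum(ys)
    fp = np.cumsum(~ys)
    keep = np.r_[np.diff(scores[order]) != 0, True]  # one point per threshold
    tpr = np.r_[0.0, tp[keep] / max(tp[-1], 1)]
    fpr = np.r_[0.0, fp[keep] / max(fp[-1], 1)]
    return fpr, tpr


class FittedPipeline:
    """One binary n-gram pipeline fit on a training split.

    Holds the training-derived state — vocabulary, optional TF-RF
    weights, selection result, feature scaler and classifier — and
    encodes unseen documents into the same feature space (tokens outside
    the training vocabulary are dropped).
    """

    def __init__(self, pipeline_config, positive_class: Hashable, negative_class: Hashable):
        self.config = pipeline_config
        self.positive_class = positive_class
        self.negative_class = negative_class
        self.vocabulary = None
        self.rf = None
        self.selection: SelectionResult | None = None
        self.scaler = None
        self.model = None

    def fit(self, docs: Sequence[TokenCounts], labels: Sequence[Hashable]) -> "FittedPipeline":
        labels = np.asarray(labels, dtype=object)
        expected = {self.positive_class, self.negative_class}
        if set(labels) != expected:
            raise ValueError(f"training labels {set(labels)} != pipeline classes {expected}")
        cfg = self.config
        self.vocabulary = build_vocabulary(docs)
        counts = count_matrix(self.vocabulary, docs)
        X = tf(counts, self.vocabulary.token_lengths(), per_order=cfg.tf_per_order)
        if cfg.weighting == "tf_rf":
            self.rf = rf_weights(counts, labels, self.positive_class)
            X = apply_tf_rf(X, self.rf)
        self.selection = select_features(
            X, counts > 0, labels,
            alpha=cfg.alpha, fraction=cfg.fraction, correction=cfg.correction,
        )
        if len(self.selection.selected) == 0:
            raise ValueError("no valid features survived selection; cannot train")
        Xs = X[:, self.selection.selected]
        if cfg.scale:
            self.scaler = StandardScaler().fit(Xs)
            Xs = self.scaler.transform(Xs)
        y = (labels == self.positive_class).astype(int)
        self.model = train_binary(Xs, y, cfg.classifier)
        return self

    def transform(self, docs: Sequence[TokenCounts]) -> np.ndarray:
        if self.selection is None:
            raise RuntimeError("pipeline is not fitted")
        counts = count_matrix(self.vocabulary, docs)
        X = tf(counts, self.vocabulary.token_lengths(), per_order=self.config.tf_per_order)
        if self.rf is not None:
            X = apply_tf_rf(X, self.rf)
        Xs = X[:, self.selection.selected]
        if self.scaler is not None:
            Xs = self.scaler.transform(Xs)
        return Xs

    def decision_scores(self, docs: Sequence[TokenCounts]) -> np.ndarray:
        """Score per document; > 0 favours the positive class."""
        return decision_scores(self.model, self.transform(docs))


def predict_ternary(models: Sequence[FittedPipeline], docs: Sequence[TokenCounts]) -> list:
    """Majority vote of three pairwise subclassifiers.

    Each subclassifier votes for one of its two classes; the class with
    most votes wins, and a 1-1-1 three-way tie is broken by the vote of
    the subclassifier with the largest absolute decision score.
    """
    if len(models) != 3 or any(m is None or m.model is None for m in models):
        raise ValueError("predict_ternary needs three fitted pairwise models")
    scores = np.vstack([m.decision_scores(docs) for m in models])  # 3 x n
    out = []
    for j in range(scores.shape[1]):
        votes = [
            m.positive_class if scores[i, j] > 0 else m.negative_class
            for i, m in enumerate(models)
        ]
        tally = Counter(votes)
        top, top_n = tally.most_common(1)[0]
        if top_n >= 2:
            out.append(top)
        else:  # 1-1-1 tie: strongest subclassifier decides
            out.append(votes[int(np.argmax(np.abs(scores[:, j])))])
    return out


@dataclass
class CVReport:
    """Aggregated cross-validation result.

    Binary reports carry pooled test scores, ROC points and the AUC;
    ternary reports carry predictions and per-class correct fractions.
    """

    kind: str
    classes: list
    n_folds: int
    seed: int
    config: dict
    fold_test_sizes: list[int]
    n_valid_per_fold: list
    n_selected_per_fold: list
    auc: float | None = None
    scores: list[float] | None = None
    y_true: list | None = None
    fpr: list[float] | None = None
    tpr: list[float] | None = None
    predictions: list | None = None
    per_class_correct: dict | None = None

    def to_dict(self) -> dict[str, Any]:
        return {k: v for k, v in self.__dict__.items() if v is not None}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def _apply_preprocessing(images, cfg) -> list[np.ndarray]:
    out = []
    for img in images:
        img = preprocess.to_grayscale(img)
        if cfg.fill_border:
            img = preprocess.fill_white_border(img, cfg.white_threshold)
        if cfg.denoise:
            img = preprocess.anisotropic_diffusion(
                img, cfg.diffusion_iterations, cfg.diffusion_kappa, cfg.diffusion_dt
            )
        out.append(img)
    return out


def images_to_docs(images, orders=(1, 2, 3)) -> list[TokenCounts]:
    """Quantize each image and extract its n-gram token bag."""
    from .ngram import extract_tokens

    return [extract_tokens(quantize(img), orders) for img in images]


def cross_validate(images, labels, config) -> CVReport:
    """Run the full pipeline under stratified k-fold cross-validation.

    Within each fold's training split the vocabulary, weights, rank-sum
    filter, ECE ranking, retention and classifier are refit from
    scratch; test documents are only ever encoded and scored.  Two or
    three classes select the binary (pooled ROC/AUC) or ternary
    (pairwise-voting, per-class recall) protocol.  Fixed seed implies
    identical folds and a byte-identical report.
    """
    labels = np.asarray(labels, dtype=object)
    if len(images) != len(labels):
        raise ValueError("images and labels length differ")
    classes = sorted(set(labels), key=str)
    if len(classes) not in (2, 3):
        raise ValueError(f"expected 2 or 3 classes, got {len(classes)}")
    min_per_class = min(Counter(labels).values())
    if min_per_class < config.n_folds:
        raise ValueError(
            f"smallest class has {min_per_class} documents; fewer than "
            f"{config.n_folds} folds"
        )

    images = _apply_preprocessing(images, config)
    docs = images_to_docs(images, config.orders)

    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    y_str = np.array([str(c) for c in labels])
    clf_seeds = np.random.SeedSequence(config.seed).generate_state(config.n_folds)

    fold_sizes, n_valid, n_selected = [], [], []
    pooled_scores, pooled_y, predictions, true_order = [], [], [], []

    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(labels)), y_str)):
        fold_cfg = replace(
            config,
            classifier=replace(config.classifier, seed=int(clf_seeds[fold]) % (2**31)),
        )
        train_docs = [docs[i] for i in tr]
        test_docs = [docs[i] for i in te]
        train_labels = labels[tr]
        fold_sizes.append(len(te))

        if len(classes) == 2:
            pipe = FittedPipeline(fold_cfg, positive_class=classes[1], negative_class=classes[0])
            pipe.fit(train_docs, train_labels)
            n_valid.append(int(pipe.selection.valid_mask.sum()))
            n_selected.append(len(pipe.selection.selected))
            pooled_scores.extend(pipe.decision_scores(test_docs).tolist())
            pooled_y.extend((labels[te] == classes[1]).astype(int).tolist())
        else:
            pipes = []
            for pos, neg in combinations(classes, 2):
                sub = np.isin(train_labels, [pos, neg])
                pipe = FittedPipeline(fold_cfg, positive_class=pos, negative_class=neg)
                pipe.fit([d for d, m in zip(train_docs, sub) if m], train_labels[sub])
                pipes.append(pipe)
            n_valid.append([int(p.selection.valid_mask.sum()) for p in pipes])
            n_selected.append([len(p.selection.selected) for p in pipes])
            predictions.extend(predict_ternary(pipes, test_docs))
            true_order.extend(labels[te].tolist())

    report = CVReport(
        kind="binary" if len(classes) == 2 else "ternary",
        classes=[str(c) for c in classes],
        n_folds=config.n_folds,
        seed=config.seed,
        config=config.to_dict(),
        fold_test_sizes=fold_sizes,
        n_valid_per_fold=n_valid,
        n_selected_per_fold=n_selected,
    )
    if len(classes) == 2:
        fpr, tpr = roc_points(pooled_scores, pooled_y)
        report.auc = roc_auc(pooled_scores, pooled_y)
        report.scores = [float(s) for s in pooled_scores]
        report.y_true = pooled_y
        report.fpr = fpr.tolist()
        report.tpr = tpr.tolist()
    else:
        report.predictions = [str(p) for p in predictions]
        report.y_true = [str(t) for t in true_order]
        report.per_class_correct = {
            str(c): float(
                np.mean([p == t for p, t in zip(predictions, true_order) if t == c])
            )
            for c in classes
        }
    return report
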