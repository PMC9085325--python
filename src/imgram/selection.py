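"""Two-step feature selection: rank-sum significance filter, then
expected-cross-entropy ranking with top-fraction retention.

Step one tests every feature column with a two-sided Wilcoxon rank-sum
(Mann-Whitney) test between the two classes and keeps only features with
p < alpha (default 0.05) — the "valid" features.  Step two scores each
valid feature by its expected cross-entropy

    ECE(t) = p(t) * sum_j p(C_j | t) * log2( p(C_j | t) / p(C_j) ),

i.e. the document frequency of the token times the KL divergence of the
class posterior given the token from the class prior, and retains the
top fraction of valid features by descending ECE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy import stats


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the two-step filter on one training set."""

    p_values: np.ndarray
    valid_mask: np.ndarray
    ece: np.ndarray
    selected: np.ndarray  # column indices, sorted by ECE descending
    alpha: float
    fraction: float

    def __post_init__(self):
        if not set(self.selected) <= set(np.flatnonzero(self.valid_mask)):
            raise ValueError("selected features must all be valid")


def ranksum_filter(
    X: np.ndarray,
    labels: Sequence[Hashable],
    alpha: float = 0.05,
    correction: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature two-sided rank-sum test between the two classes.

    Uses the normal approximation with tie (and continuity) correction.
    A feature constant across both groups gets p = 1 and is never valid.

    Parameters
    ----------
    X
        Documents x features value matrix (weighted feature values).
    labels
        One label per document; exactly two distinct labels required,
        each with at least two documents.
    alpha
        Significance level; valid features have p < alpha.
    correction
        ``"bh"`` applies Benjamini-Hochberg FDR adjustment to the
        p-values before thresholding; default is the raw filter.

    Returns
    -------
    (p_values, valid_mask)
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels, dtype=object)
    classes = sorted(set(labels), key=str)
    if len(classes) != 2:
        raise ValueError(f"rank-sum filter needs exactly 2 classes, got {len(classes)}")
    g1 = X[labels == classes[0]]
    g2 = X[labels == classes[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need >= 2 documents per class")

    p = np.ones(X.shape[1])
    # a column constant over both groups carries no information: p = 1
    varying = (X.max(axis=0) - X.min(axis=0)) > 0
    if varying.any():
        res = stats.mannwhitneyu(
            g1[:, varying], g2[:, varying], alternative="two-sided",
            method="asymptotic", axis=0,
        )
        p[varying] = np.clip(res.pvalue, 0.0, 1.0)
    if correction == "bh":
        p = stats.false_discovery_control(p)
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    return p, p < alpha


def ece_scores(
    presence: np.ndarray | sp.spmatrix,
    labels: Sequence[Hashable],
    valid_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Expected cross-entropy of each feature from document presence.

    ``presence[j, i]`` is truthy iff document j contains feature i;
    p(t) is the fraction of documents containing the token, the class
    posterior p(C|t) is estimated among those documents, and the prior
    p(C) from the training labels.  Terms with zero posterior contribute
    nothing; an absent feature (p(t) = 0) scores 0.  When ``valid_mask``
    is given, invalid features score 0 without being computed.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) == 0:
        raise ValueError("empty training set")
    if sp.issparse(presence):
        presence = presence.toarray()
    presence = np.asarray(presence) > 0
    if presence.shape[0] != len(labels):
        raise ValueError("presence rows and labels length differ")
    classes = sorted(set(labels), key=str)
    if len(classes) < 2:
        raise ValueError("ECE needs >= 2 classes")

    n_docs = len(labels)
    n_t = presence.sum(axis=0).astype(float)
    p_t = n_t / n_docs
    scores = np.zeros(presence.shape[1])
    safe_n_t = np.maximum(n_t, 1)
    for cls in classes:
        in_cls = labels == cls
        prior = in_cls.mean()
        post = presence[in_cls].sum(axis=0) / safe_n_t
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(post > 0, post * np.log2(post / prior), 0.0)
        scores += term
    scores *= p_t
    scores = np.maximum(scores, 0.0)  # clip -0.0 / rounding noise
    if valid_mask is not None:
        scores = np.where(valid_mask, scores, 0.0)
    return scores


def select_top_fraction(
    p_values: np.ndarray,
    valid_mask: np.ndarray,
    ece: np.ndarray,
    fraction: float,
    alpha: float = 0.05,
) -> SelectionResult:
    """Retain the top fraction of valid features by descending ECE.

    Keeps max(1, floor(fraction * n_valid)) features; ties in ECE are
    broken by vocabulary (column) order.  With no valid features an
    empty selection is returned with a warning.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    valid = np.flatnonzero(valid_mask)
    if len(valid) == 0:
        warnings.warn("no feature passed the rank-sum filter; empty selection")
        selected = np.array([], dtype=int)
    else:
        order = valid[np.lexsort((valid, -ece[valid]))]
        k = max(1, int(np.floor(fraction * len(valid))))
        selected = order[:k]
    return SelectionResult(
        p_values=np.asarray(p_values),
        valid_mask=np.asarray(valid_mask),
        ece=np.asarray(ece),
        selected=selected,
        alpha=alpha,
        fraction=fraction,
    )


def select_features(
    X: np.ndarray,
    presence: np.ndarray | sp.spmatrix,
    labels: Sequence[Hashable],
    alpha: float = 0.05,
    fraction: float = 1.0,
    correction: str | None = None,
) -> SelectionResult:
    """Run both selection steps on one (binary) training set."""
    p, valid = ranksum_filter(X, labels, alpha=alpha, correction=correction)
    ece = ece_scores(presence, labels, valid)
    return select_top_fraction(p, valid, ece, fraction, alpha=alpha)
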