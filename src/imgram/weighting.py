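"""Term weighting: TF and supervised TF-RF feature values.

TF is a token's count in a document divided by the document's total
token count (all n-gram orders pooled into one bag by default).  RF is
the relevance factor log2(2 + a / max(1, c)), where a and c count the
positive and negative training documents containing the token, and the
imbalance-adjusted TF-RF multiplies TF by log2(2 + (N/P) * a / max(1, c))
with P and N the positive and negative training-document totals.  The
per-token factors are always derived from training labels only and then
reapplied verbatim to test documents.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np
import scipy.sparse as sp


def tf(
    counts: sp.spmatrix,
    token_lengths: np.ndarray | None = None,
    per_order: bool = False,
) -> np.ndarray:
    """Term-frequency matrix: each count divided by its document total.

    Parameters
    ----------
    counts
        Documents x tokens occurrence-count matrix.
    token_lengths, per_order
        With ``per_order=True`` each n-gram order is normalized as its own
        bag (denominator = the document's total count of tokens of that
        length); requires ``token_lengths``.  Default pools all orders.

    Documents with zero tokens get an all-zero row.
    """
    counts = sp.csr_matrix(counts, dtype=np.float64)
    dense = counts.toarray()
    if per_order:
        if token_lengths is None:
            raise ValueError("per-order TF requires token_lengths")
        token_lengths = np.asarray(token_lengths)
        out = np.zeros_like(dense)
        for n in np.unique(token_lengths):
            cols = token_lengths == n
            block = dense[:, cols]
            denom = block.sum(axis=1, keepdims=True)
            out[:, cols] = np.divide(
                block, denom, out=np.zeros_like(block), where=denom > 0
            )
        return out
    denom = dense.sum(axis=1, keepdims=True)
    return np.divide(dense, denom, out=np.zeros_like(dense), where=denom > 0)


@dataclass(frozen=True)
class RfWeights:
    """Per-token relevance-frequency statistics from a binary training set.

    ``a`` / ``c`` are per-token counts of positive / negative documents
    containing the token; ``P`` / ``N`` are the training totals.
    """

    positive_class: Hashable
    a: np.ndarray
    c: np.ndarray
    P: int
    N: int

    def __post_init__(self):
        if self.P <= 0 or self.N <= 0:
            raise ValueError("need at least one positive and one negative document")
        if (self.a > self.P).any() or (self.c > self.N).any():
            raise ValueError("document counts exceed class totals")
        if (self.a < 0).any() or (self.c < 0).any():
            raise ValueError("document counts must be nonnegative")

    @property
    def rf(self) -> np.ndarray:
        """Relevance factor log2(2 + a / max(1, c)); always >= 1."""
        return np.log2(2.0 + self.a / np.maximum(1, self.c))

    @property
    def tf_rf_factor(self) -> np.ndarray:
        """Imbalance-adjusted factor log2(2 + (N/P) * a / max(1, c))."""
        return np.log2(2.0 + (self.N / self.P) * self.a / np.maximum(1, self.c))


def rf_weights(
    counts: sp.spmatrix,
    labels: Sequence[Hashable],
    positive_class: Hashable,
) -> RfWeights:
    """Compute per-token RF statistics from training counts and labels.

    Presence, not raw frequency, is what enters a and c: a document
    contains a token iff its count is > 0.
    """
    labels = np.asarray(labels, dtype=object)
    if counts.shape[0] != len(labels):
        raise ValueError("counts rows and labels length differ")
    pos = labels == positive_class
    if not pos.any() or pos.all():
        raise ValueError(
            "rf_weights needs >= 1 positive and >= 1 negative training document"
        )
    presence = (sp.csr_matrix(counts) > 0).astype(np.int64)
    a = np.asarray(presence[pos].sum(axis=0)).ravel()
    c = np.asarray(presence[~pos].sum(axis=0)).ravel()
    return RfWeights(positive_class, a, c, int(pos.sum()), int((~pos).sum()))


def tf_rf(
    counts: sp.spmatrix,
    labels: Sequence[Hashable],
    positive_class: Hashable,
) -> tuple[np.ndarray, RfWeights]:
    """TF-RF feature matrix for a binary training set.

    Returns the weighted matrix together with the fitted
    :class:`RfWeights`, which must be reused (via :func:`apply_tf_rf`)
    to weight test documents without label leakage.
    """
    weights = rf_weights(counts, labels, positive_class)
    return apply_tf_rf(tf(counts), weights), weights


def apply_tf_rf(tf_matrix: np.ndarray, weights: RfWeights) -> np.ndarray:
    """Scale a TF matrix column-wise by training-derived TF-RF factors."""
    if tf_matrix.shape[1] != len(weights.a):
        raise ValueError("TF matrix width does not match RF weights")
    return tf_matrix * weights.tf_rf_factor
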