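"""Row-wise n-gram token extraction, vocabulary and count matrix.

A quantized image is treated as a document: a window of length n slides
left to right along each row of the character matrix (stride 1, no wrap
across rows, no vertical windows), and every window is one token.  With
orders {1, 2, 3} over a 16-letter alphabet the vocabulary is bounded by
16 + 16^2 + 16^3 = 4368 distinct tokens.  The vocabulary is always built
from the training documents only; tokens first seen at test time are not
representable and are dropped.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

DEFAULT_ORDERS = frozenset({1, 2, 3})


def window_tokens(symbols: Sequence[str], n: int, sep: str = "") -> list[str]:
    """All length-``n`` sliding windows over a symbol sequence, in order.

    Each window is joined with ``sep`` into one token string.  A sequence
    shorter than ``n`` yields no tokens.
    """
    if n < 1:
        raise ValueError(f"window length must be >= 1, got {n}")
    return [sep.join(symbols[i : i + n]) for i in range(len(symbols) - n + 1)]


@dataclass(frozen=True)
class TokenCounts:
    """Multiset of n-gram tokens observed in one document (image)."""

    counts: dict[str, int]
    total_tokens: int = field(default=-1)

    def __post_init__(self):
        total = sum(self.counts.values())
        if self.total_tokens == -1:
            object.__setattr__(self, "total_tokens", total)
        elif self.total_tokens != total:
            raise ValueError("total_tokens does not match sum of counts")


def _check_orders(orders: Iterable[int]) -> list[int]:
    orders = sorted(set(orders))
    if not orders:
        raise ValueError("orders must be a nonempty subset of {1, 2, 3}")
    if not set(orders) <= {1, 2, 3}:
        raise ValueError(f"unsupported n-gram orders {orders}; allowed: 1, 2, 3")
    return orders


def extract_tokens(cm: np.ndarray, orders: Iterable[int] = DEFAULT_ORDERS) -> TokenCounts:
    """Extract row-wise n-gram tokens from a character matrix.

    For each row of width W and each order n with W >= n, the W - n + 1
    contiguous windows are emitted; counts are pooled over the whole
    matrix into one bag.
    """
    orders = _check_orders(orders)
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.size == 0:
        raise ValueError(f"expected a nonempty 2-D character matrix, got shape {cm.shape}")
    counter: Counter[str] = Counter()
    for row in cm:
        s = "".join(row)
        for n in orders:
            counter.update(window_tokens(s, n))
    return TokenCounts(dict(counter))


def _token_sort_key(token: str) -> tuple[int, str]:
    return (len(token), token)


@dataclass(frozen=True)
class Vocabulary:
    """Ordered set of distinct tokens; defines feature-vector columns.

    Ordering is deterministic: by token length, then lexicographic —
    so column indices are reproducible across runs and independent of
    training-document order.
    """

    tokens: tuple[str, ...]
    index: dict[str, int] = field(default=None, repr=False)

    def __post_init__(self):
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("vocabulary contains duplicate tokens")
        object.__setattr__(
            self, "index", {t: i for i, t in enumerate(self.tokens)}
        )

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def token_lengths(self) -> np.ndarray:
        return np.array([len(t) for t in self.tokens])


def build_vocabulary(train_docs: Sequence[TokenCounts]) -> Vocabulary:
    """Union of all tokens seen in the training documents, ordered.

    The vocabulary fixes the feature space: test-time tokens outside it
    are dropped by :func:`count_matrix`.
    """
    if not train_docs:
        raise ValueError("cannot build a vocabulary from zero documents")
    tokens: set[str] = set()
    for doc in train_docs:
        tokens.update(doc.counts)
    return Vocabulary(tuple(sorted(tokens, key=_token_sort_key)))


def count_matrix(vocab: Vocabulary, docs: Sequence[TokenCounts]) -> sp.csr_matrix:
    """Sparse documents x tokens occurrence-count matrix.

    Entry (j, i) is the count of vocabulary token i in document j; tokens
    of a document absent from the vocabulary contribute nothing.
    """
    data, indices, indptr = [], [], [0]
    for doc in docs:
        cols = []
        for token, cnt in doc.counts.items():
            col = vocab.index.get(token)
            if col is not None:
                cols.append((col, cnt))
        cols.sort()
        indices.extend(c for c, _ in cols)
        data.extend(n for _, n in cols)
        indptr.append(len(indices))
    return sp.csr_matrix(
        (np.array(data, dtype=np.int64), np.array(indices, dtype=np.int64), indptr),
        shape=(len(docs), len(vocab)),
    )
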