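"""Synthetic textured-image datasets with planted horizontal gray-level motifs.

Each class is described by a :class:`ClassSpec`: background pixels are
drawn i.i.d. uniform over the gray ranges of a set of quantization bins,
and short horizontal "motifs" — runs of 2-3 specific bins — are planted
at random row positions.  After quantization, a motif becomes a fixed
letter string, so its n-gram windows are class-discriminative tokens
with known ground truth (``truth_tokens``).  This makes every stage of
the pipeline (extraction, weighting, selection, classification)
testable without clinical images.

The generator deliberately keeps the null exchangeable: classes share
the same background-bin set by default, so any feature not derived from
a motif has the same distribution in every class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np

from .encode import ALPHABET, BIN_WIDTH
from .ngram import window_tokens

N_BINS = len(ALPHABET)


@dataclass(frozen=True)
class ClassSpec:
    """Recipe for one synthetic class.

    Parameters
    ----------
    label
        Class identifier.
    background_bins
        Quantization-bin indices (0-15) from which background pixels are
        drawn.
    motif
        Sequence of 2-3 bin indices planted as a horizontal run.
    motif_rate
        Expected number of planted motifs per image row (Poisson).
    """

    label: Hashable
    background_bins: frozenset[int]
    motif: tuple[int, ...]
    motif_rate: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "background_bins", frozenset(self.background_bins))
        object.__setattr__(self, "motif", tuple(self.motif))
        if not self.background_bins:
            raise ValueError("background_bins must be nonempty")
        bins = self.background_bins | set(self.motif)
        if any(not 0 <= b < N_BINS for b in bins):
            raise ValueError(f"bin indices must lie in [0, {N_BINS - 1}]")
        if len(self.motif) not in (2, 3):
            raise ValueError("motif length must be 2 or 3")
        if self.motif_rate < 0:
            raise ValueError("motif_rate must be >= 0")

    @property
    def motif_string(self) -> str:
        """The motif's letter string after quantization."""
        return "".join(ALPHABET[b] for b in self.motif)

    def truth_tokens(self, orders: Sequence[int] = (1, 2, 3)) -> frozenset[str]:
        """All n-gram windows of the motif string for the given orders."""
        tokens: set[str] = set()
        for n in orders:
            tokens.update(window_tokens(self.motif_string, n))
        return frozenset(tokens)


@dataclass(frozen=True)
class SyntheticDataset:
    """Labeled images plus the per-class planted-token ground truth."""

    images: tuple[np.ndarray, ...]
    labels: tuple[Hashable, ...]
    truth_tokens: dict[Hashable, frozenset[str]] = field(repr=False)

    def __post_init__(self):
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must have equal length")

    def __len__(self) -> int:
        return len(self.images)


def _bin_gray(rng: np.random.Generator, bins: np.ndarray) -> np.ndarray:
    """Uniform gray values inside each pixel's assigned bin."""
    return bins * BIN_WIDTH + rng.integers(0, BIN_WIDTH, size=bins.shape)


def make_image(spec: ClassSpec, height: int, width: int, seed: int) -> np.ndarray:
    """Generate one labeled synthetic image.

    Background pixels are i.i.d. uniform over the union of the
    background bins' gray ranges; motifs are planted at Poisson-
    distributed counts per row with uniform non-wrapping start columns.
    Identical arguments give byte-identical images.
    """
    if height < 1 or width < len(spec.motif):
        raise ValueError(
            f"image must be >= 1 x {len(spec.motif)} for this spec, "
            f"got {height} x {width}"
        )
    rng = np.random.default_rng(seed)
    bg = rng.choice(sorted(spec.background_bins), size=(height, width))
    img = _bin_gray(rng, bg)
    if spec.motif_rate > 0:
        motif = np.array(spec.motif)
        m = len(motif)
        for r in range(height):
            for _ in range(rng.poisson(spec.motif_rate)):
                start = rng.integers(0, width - m + 1)
                img[r, start : start + m] = _bin_gray(rng, motif)
    return img.astype(np.uint8)


def make_dataset(
    specs: Sequence[ClassSpec],
    n_per_class: int | Sequence[int],
    shape: tuple[int, int] = (32, 32),
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a labeled dataset with ``n_per_class`` images per spec.

    ``n_per_class`` may be a single count or one count per spec (class
    imbalance).  Per-image seeds are split deterministically from
    ``seed``, so identical arguments reproduce the dataset exactly.
    """
    if len(specs) < 2:
        raise ValueError("need >= 2 class specs")
    labels_seen = [s.label for s in specs]
    if len(set(labels_seen)) != len(labels_seen):
        raise ValueError(f"duplicate class labels in specs: {labels_seen}")
    if np.isscalar(n_per_class):
        counts = [int(n_per_class)] * len(specs)
    else:
        counts = [int(n) for n in n_per_class]
        if len(counts) != len(specs):
            raise ValueError("one count per spec required")
    if any(n < 1 for n in counts):
        raise ValueError("n_per_class must be >= 1")

    child_seeds = np.random.SeedSequence(seed).generate_state(sum(counts))
    images, labels = [], []
    i = 0
    for spec, n in zip(specs, counts):
        for _ in range(n):
            images.append(make_image(spec, shape[0], shape[1], int(child_seeds[i])))
            labels.append(spec.label)
            i += 1
    truth = {s.label: s.truth_tokens() for s in specs}
    return SyntheticDataset(tuple(images), tuple(labels), truth)


def two_class_specs(motif_rate: float = 1.0) -> list[ClassSpec]:
    """Default binary study conditions: shared background bins 0-7,
    bin-disjoint class motifs KLM (bins 10-12) vs NOP (bins 13-15)."""
    bg = frozenset(range(8))
    return [
        ClassSpec("class_a", bg, (10, 11, 12), motif_rate),
        ClassSpec("class_b", bg, (13, 14, 15), motif_rate),
    ]


def three_class_specs(motif_rate: float = 1.0) -> list[ClassSpec]:
    """Default ternary study conditions with three bin-disjoint motifs."""
    bg = frozenset(range(8))
    return [
        ClassSpec("class_a", bg, (8, 9, 8), motif_rate),
        ClassSpec("class_b", bg, (10, 11, 12), motif_rate),
        ClassSpec("class_c", bg, (13, 14, 15), motif_rate),
    ]
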