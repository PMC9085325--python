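"""Gray-level quantization of an image into a 16-letter character matrix.

Every gray value in [0, 255] falls into one of sixteen consecutive
16-level bins; bin ``k`` is labelled with the ``k``-th capital letter, so
``[0, 15] -> A``, ``[16, 31] -> B``, ..., ``[240, 255] -> P``.  The
quantized matrix is the "text" from which row-wise n-gram tokens are
extracted downstream.
"""

from __future__ import annotations

import numpy as np

#: The 16-letter quantization alphabet, in bin order.
ALPHABET = "ABCDEFGHIJKLMNOP"

#: Width of each gray-level bin.
BIN_WIDTH = 16

_LETTER_ARRAY = np.array(list(ALPHABET))


def letter_of(gray_value: int) -> str:
    """Return the quantization letter for a single integer gray value.

    Parameters
    ----------
    gray_value
        Integer intensity in [0, 255].

    Returns
    -------
    str
        One of the letters ``A``..``P``; monotone non-decreasing in the
        input (in alphabet order).

    Raises
    ------
    ValueError
        If the value is out of range.
    TypeError
        If the value is not an integer (quantization is defined on
        integer gray levels; values are never silently rounded).
    """
    if isinstance(gray_value, bool) or not isinstance(
        gray_value, (int, np.integer)
    ):
        raise TypeError(
            f"gray value must be an integer, got {type(gray_value).__name__}"
        )
    if not 0 <= gray_value <= 255:
        raise ValueError(f"gray value {gray_value} outside [0, 255]")
    return ALPHABET[int(gray_value) // BIN_WIDTH]


def validate_gray_image(img: np.ndarray) -> np.ndarray:
    """Check that ``img`` is a valid 2-D integer gray image in [0, 255]."""
    arr = np.asarray(img)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"expected a nonempty 2-D image, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise TypeError(
            f"gray image must have an integer dtype, got {arr.dtype}"
        )
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("gray image values must lie in [0, 255]")
    return arr


def quantize(img: np.ndarray) -> np.ndarray:
    """Quantize a gray image elementwise into a character matrix.

    Parameters
    ----------
    img
        2-D integer array with values in [0, 255].

    Returns
    -------
    numpy.ndarray
        Array of single-character strings (dtype ``<U1``) with the same
        shape as ``img``; every entry is one of ``A``..``P``.
    """
    arr = validate_gray_image(img)
    return _LETTER_ARRAY[arr // BIN_WIDTH]


def bin_midpoints(cm: np.ndarray) -> np.ndarray:
    """Map a character matrix back to the midpoint gray value of each bin.

    Useful for quantifying information loss: the reconstruction differs
    from the source image by at most half a bin width per pixel.
    """
    idx = np.vectorize(ALPHABET.index, otypes=[int])(cm)
    return idx * BIN_WIDTH + (BIN_WIDTH - 1) / 2


def write_char_matrix(cm: np.ndarray, path) -> None:
    """Write a character matrix as plain text, one row per line."""
    with open(path, "w") as fh:
        for row in cm:
            fh.write("".join(row) + "\n")


def read_char_matrix(path) -> np.ndarray:
    """Read a character matrix written by :func:`write_char_matrix`."""
    with open(path) as fh:
        rows = [list(line.rstrip("\n")) for line in fh if line.strip()]
    cm = np.array(rows, dtype="<U1")
    if cm.ndim != 2:
        raise ValueError(f"ragged or empty character matrix in {path}")
    bad = ~np.isin(cm, list(ALPHABET))
    if bad.any():
        raise ValueError(f"invalid letters in {path}")
    return cm
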