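"""File-format plumbing: images, labels tables, vocabulary TSVs and
sparse MatrixMarket feature stores."""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from PIL import Image

from .ngram import Vocabulary
from .preprocess import to_grayscale


def load_image(path) -> np.ndarray:
    """Read a PNG/TIFF/BMP/JPEG image as an integer gray image."""
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB") if im.mode not in ("L", "I;16", "I") else im)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image {path!s}: {exc}") from exc
    if arr.ndim == 3:
        return to_grayscale(arr[..., :3])
    return to_grayscale(arr.astype(np.int64).clip(0, 255).astype(np.uint8))


def save_image(img: np.ndarray, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.asarray(img, dtype=np.uint8), mode="L").save(path)


def read_labels_table(path) -> tuple[list[str], list[str]]:
    """Read a labels TSV with columns ``path`` and ``label``.

    Image paths are resolved relative to the table's directory.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"path", "label"} - set(table.columns)
    if missing:
        raise ValueError(f"labels table {path!s} lacks columns: {sorted(missing)}")
    base = Path(path).parent
    paths = [str(p) if os.path.isabs(p) else str(base / p) for p in table["path"]]
    return paths, table["label"].tolist()


def write_labels_table(paths: Sequence[str], labels: Sequence[str], out_path) -> None:
    Path(out_path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"path": paths, "label": labels}).to_csv(out_path, sep="\t", index=False)


def save_vocabulary(vocab: Vocabulary, path) -> None:
    """Vocabulary as TSV (token, index)."""
    pd.DataFrame({"token": vocab.tokens, "index": range(len(vocab))}).to_csv(
        path, sep="\t", index=False
    )


def load_vocabulary(path) -> Vocabulary:
    table = pd.read_csv(path, sep="\t", dtype={"token": str, "index": int})
    tokens = table.sort_values("index")["token"].tolist()
    return Vocabulary(tuple(tokens))


def save_feature_store(matrix, vocab: Vocabulary, doc_ids: Sequence[str], out_dir) -> None:
    """Persist a count/feature matrix with its vocabulary and document ids.

    The matrix goes to ``matrix.mtx`` (MatrixMarket), the vocabulary to
    ``vocabulary.tsv`` and the row ids to ``documents.txt``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out / "matrix.mtx"), sp.coo_matrix(matrix))
    save_vocabulary(vocab, out / "vocabulary.tsv")
    (out / "documents.txt").write_text("\n".join(map(str, doc_ids)) + "\n")


def load_feature_store(in_dir) -> tuple[sp.csr_matrix, Vocabulary, list[str]]:
    src = Path(in_dir)
    matrix = sp.csr_matrix(scipy.io.mmread(str(src / "matrix.mtx")))
    vocab = load_vocabulary(src / "vocabulary.tsv")
    doc_ids = (src / "documents.txt").read_text().splitlines()
    return matrix, vocab, doc_ids


def save_selection_tsv(vocab: Vocabulary, result, path) -> None:
    """Audit table: token, p_value, ece, selected_flag."""
    selected = np.zeros(len(vocab), dtype=bool)
    selected[result.selected] = True
    pd.DataFrame(
        {
            "token": vocab.tokens,
            "p_value": result.p_values,
            "ece": result.ece,
            "selected_flag": selected.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)
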