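"""Literature-semantic similarity providers.

The literature signal enters the pipeline as a drug-drug and a
disease-disease similarity matrix.  Two interchangeable providers are
offered:

* :func:`load_precomputed_literature_sim` — read a matrix produced by any
  external language model over an article corpus;
* :func:`cooccurrence_similarity` — a lightweight provider that builds the
  matrix from per-entity text with TF-IDF bag-of-words cosine similarity.

Both return a :class:`~lbmff.similarity.SimilarityMatrix`, so swapping
providers changes nothing downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_data import ValidationError
from .similarity import SimilarityMatrix

__all__ = [
    "EntityCorpus",
    "load_precomputed_literature_sim",
    "cooccurrence_similarity",
]

_CLAMP_TOL = 1e-9


@dataclass
class EntityCorpus:
    """Per-entity concatenated text (titles/abstracts mentioning the entity)."""

    ids: tuple[str, ...]
    texts: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.texts):
            raise ValidationError("corpus ids and texts differ in length")

    @classmethod
    def from_mapping(cls, corpus: dict[str, str], ids=None) -> "EntityCorpus":
        if ids is None:
            ids = tuple(corpus)
        return cls(tuple(ids), tuple(corpus.get(i, "") for i in ids))

    def empty_entities(self) -> tuple[str, ...]:
        return tuple(i for i, t in zip(self.ids, self.texts) if not t.strip())


def load_precomputed_literature_sim(
    path, labels: tuple[str, ...] | list[str], measure: str = "literature"
) -> SimilarityMatrix:
    """Read an externally computed similarity matrix and fit it to a catalog.

    File ids must be a subset of ``labels``; entities missing from the file
    get zero off-diagonal similarity and 1 on the diagonal.  An input that
    is asymmetric beyond 1e-9 is symmetrized as (S + S^T)/2 with a warning.
    Values outside [0, 1] by more than a tiny clamping tolerance raise.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValidationError(f"{path}: row and column ids differ")
    extra = set(df.index) - set(labels)
    if extra:
        raise ValidationError(f"{path}: ids not in catalog: {sorted(extra)[:5]}")
    raw = df.to_numpy(dtype=float)
    if raw.size and (raw.min() < -_CLAMP_TOL or raw.max() > 1 + _CLAMP_TOL):
        raise ValidationError(f"{path}: similarity values outside [0, 1]")
    if not np.allclose(raw, raw.T, rtol=0, atol=1e-9):
        warnings.warn(f"{path}: asymmetric input symmetrized as (S + S^T)/2")
    raw = (raw + raw.T) / 2.0
    np.clip(raw, 0.0, 1.0, out=raw)

    k = len(labels)
    S = np.eye(k)
    pos = {d: i for i, d in enumerate(labels)}
    idx = np.array([pos[d] for d in df.index], dtype=int)
    S[np.ix_(idx, idx)] = raw
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(S, tuple(labels), measure)


def cooccurrence_similarity(
    corpus: EntityCorpus,
    measure: str = "literature",
    use_idf: bool = True,
    lowercase: bool = True,
) -> SimilarityMatrix:
    """TF-IDF bag-of-words cosine similarity between entity texts.

    Entities with empty text keep the empty-profile convention (diagonal
    1, off-diagonal 0).  Deterministic given the tokenizer configuration;
    ``use_idf=False`` gives plain L2-normalized term-frequency cosine.
    """
    from sklearn.feature_extraction.text import TfidfVectorizer

    nonempty = [i for i, t in enumerate(corpus.texts) if t.strip()]
    if len(nonempty) < 2:
        raise ValidationError("corpus must contain >= 2 entities with text")
    vec = TfidfVectorizer(
        lowercase=lowercase,
        token_pattern=r"(?u)\b\w+\b",  # keep single-character tokens
        use_idf=use_idf,
        norm="l2",
    )
    X = vec.fit_transform([corpus.texts[i] for i in nonempty])
    C = (X @ X.T).toarray()

    k = len(corpus.ids)
    S = np.eye(k)
    idx = np.array(nonempty, dtype=int)
    S[np.ix_(idx, idx)] = C
    np.clip(S, 0.0, 1.0, out=S)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(S, corpus.ids, measure)
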