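"""Word-vector semantic spaces: LSA construction, loading, and geometry.

A semantic space maps a vocabulary of normalized tokens to real vectors of a
fixed dimensionality K.  Proximity of two vectors (cosine of their angle)
encodes contextual similarity of meaning; the Euclidean norm of a vector
("vector length") tracks the information value of a word — very frequent
words end up with shorter vectors.

Two routes produce a space:

* the *builder* route: a tokenized corpus -> term-document count matrix ->
  log-entropy weighting -> truncated SVD, with word vectors taken as rows of
  ``U_k @ diag(s_k)`` so that vector length reflects term salience;
* the *loader* route: a word2vec-style text file (optional ``"<n> <k>"``
  header, then one ``token v1 ... vk`` line per word), e.g. a pretrained
  space such as the German-Wikipedia ``de_wiki`` space (526,004 words x 400
  dimensions).
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Corpus",
    "TermDocMatrix",
    "SemanticSpace",
    "normalize_token",
    "build_cooccurrence",
    "log_entropy_weight",
    "embed_svd",
    "build_space",
    "load_space",
    "write_space",
    "cosine",
    "vector_length",
]

# strip leading/trailing non-word characters only; \w covers umlauts and ss
_EDGE_PUNCT = re.compile(r"^[\W_]+|[\W_]+$", re.UNICODE)


def normalize_token(raw: str) -> str:
    """Normalize a raw token: NFC, lowercase, strip surrounding punctuation.

    Internal characters (umlauts, eszett, hyphens inside compounds) are
    preserved.  May return ``""`` for punctuation-only input; downstream
    coding treats an empty token as out of vocabulary.
    """
    return _EDGE_PUNCT.sub("", unicodedata.normalize("NFC", raw).strip().lower())


@dataclass(frozen=True)
class Corpus:
    """An ordered collection of tokenized documents."""

    documents: tuple[tuple[str, ...], ...]

    @classmethod
    def from_documents(cls, docs: Iterable[Iterable[str]]) -> "Corpus":
        documents = tuple(tuple(normalize_token(t) for t in doc) for doc in docs)
        if not documents:
            raise ValueError("empty corpus")
        for doc in documents:
            if any(t == "" for t in doc):
                raise ValueError("corpus contains empty tokens after normalization")
        return cls(documents)

    @classmethod
    def from_text_file(cls, path: str | Path) -> "Corpus":
        """One document per line, whitespace tokenization, UTF-8."""
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        docs = [ln.split() for ln in lines if ln.strip()]
        return cls.from_documents(docs)


@dataclass(frozen=True)
class TermDocMatrix:
    """Term-by-document count matrix with an ordered vocabulary."""

    terms: tuple[str, ...]
    counts: np.ndarray  # (n_terms, n_docs), nonnegative ints

    def __post_init__(self) -> None:
        if len(self.terms) != self.counts.shape[0]:
            raise ValueError("terms/counts row mismatch")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate terms")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")


@dataclass
class SemanticSpace:
    """Vocabulary-to-vector mapping with fixed dimensionality.

    Lookup is exact-match on normalized tokens.
    """

    vocabulary: tuple[str, ...]
    vectors: np.ndarray  # (|vocab|, K)
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.vocabulary):
            raise ValueError("vocabulary size must equal number of vector rows")
        if self.vectors.shape[1] < 1:
            raise ValueError("dimensionality K must be >= 1")
        self._index = {tok: i for i, tok in enumerate(self.vocabulary)}
        if len(self._index) != len(self.vocabulary):
            raise ValueError("duplicate tokens in vocabulary")

    @property
    def k(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return len(self.vocabulary)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def vector(self, token: str) -> np.ndarray:
        try:
            return self.vectors[self._index[token]]
        except KeyError:
            raise KeyError(f"token not in semantic space: {token!r}") from None


def build_cooccurrence(corpus: Corpus) -> TermDocMatrix:
    """Count term occurrences per document; vocabulary sorted lexicographically."""
    if not corpus.documents:
        raise ValueError("empty corpus")
    terms = tuple(sorted({t for doc in corpus.documents for t in doc}))
    index = {t: i for i, t in enumerate(terms)}
    counts = np.zeros((len(terms), len(corpus.documents)), dtype=int)
    for d, doc in enumerate(corpus.documents):
        for tok in doc:
            counts[index[tok], d] += 1
    return TermDocMatrix(terms, counts)


def log_entropy_weight(m: TermDocMatrix) -> np.ndarray:
    """Log-entropy weighting of a term-document matrix.

    ``w[t, d] = log(1 + counts[t, d]) * (1 - H(t) / log(n_docs))`` where
    ``H(t)`` is the entropy (natural log) of the term's distribution over
    documents.  A term concentrated in one document gets global weight 1, a
    term spread uniformly over all documents gets 0.
    """
    n_docs = m.counts.shape[1]
    if n_docs < 2:
        raise ValueError("log-entropy weighting needs at least 2 documents")
    counts = m.counts.astype(float)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals > 0, counts / totals, 0.0)
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    entropy = -plogp.sum(axis=1)
    global_weight = 1.0 - entropy / np.log(n_docs)
    global_weight = np.where(totals[:, 0] > 0, global_weight, 0.0)
    return np.log1p(counts) * global_weight[:, None]


def embed_svd(weighted: np.ndarray, terms: Sequence[str], k: int) -> SemanticSpace:
    """Truncated-SVD embedding: word vectors are rows of ``U_k @ diag(s_k)``.

    The sign of each left singular vector is fixed by forcing its
    largest-magnitude entry positive, so the embedding is deterministic.
    ``k`` must not exceed the numerical rank (no zero-padding): at full rank
    pairwise row cosines of the embedding equal those of ``weighted``.
    """
    weighted = np.asarray(weighted, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    u, s, _ = np.linalg.svd(weighted, full_matrices=False)
    tol = s[0] * max(weighted.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int(np.sum(s > tol))
    if k > rank:
        raise ValueError(f"k={k} exceeds numerical rank {rank}")
    u = u[:, :k].copy()
    for j in range(k):
        i_max = int(np.argmax(np.abs(u[:, j])))
        if u[i_max, j] < 0:
            u[:, j] = -u[:, j]
    return SemanticSpace(tuple(terms), u * s[:k])


def build_space(corpus: Corpus, k: int) -> SemanticSpace:
    """Builder route: counts -> log-entropy weighting -> truncated SVD."""
    m = build_cooccurrence(corpus)
    return embed_svd(log_entropy_weight(m), m.terms, k)


def load_space(path: str | Path) -> SemanticSpace:
    """Load a word2vec-text-dialect space (optional ``"<n> <k>"`` header).

    Tokens are normalized on load; duplicates after normalization and
    inconsistent dimensionality are errors.
    """
    path = Path(path)
    tokens: list[str] = []
    rows: list[np.ndarray] = []
    k: int | None = None
    declared: tuple[int, int] | None = None
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if lineno == 1 and len(parts) == 2:
                try:
                    declared = (int(parts[0]), int(parts[1]))
                    continue
                except ValueError:
                    pass  # first line is a data line with K=1
            token = normalize_token(parts[0])
            try:
                values = np.array([float(v) for v in parts[1:]], dtype=float)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric vector entry") from exc
            if k is None:
                k = values.size
                if k < 1:
                    raise ValueError(f"{path}:{lineno}: line has no vector values")
            elif values.size != k:
                raise ValueError(
                    f"{path}:{lineno}: inconsistent dimensionality "
                    f"({values.size} values, expected {k})"
                )
            if token in set(tokens):
                raise ValueError(f"duplicate token in space file: {token!r}")
            tokens.append(token)
            rows.append(values)
    if not rows:
        raise ValueError(f"{path}: no word vectors found")
    if declared is not None:
        if declared[0] != len(rows) or declared[1] != k:
            raise ValueError(
                f"{path}: header declares {declared[0]} x {declared[1]}, "
                f"file has {len(rows)} x {k}"
            )
    return SemanticSpace(tuple(tokens), np.vstack(rows))


def write_space(
    space: SemanticSpace,
    path: str | Path,
    header: bool = True,
    precision: int | None = None,
) -> None:
    """Write a space in the word2vec text dialect.

    With ``precision=None`` values are written with ``repr``-level precision
    (``%.17g``) so ``load_space(write_space(s))`` reproduces the vectors
    bit-identically; ``precision=8`` gives compact 8-significant-digit
    decimals (idempotent after one round trip).
    """
    fmt = f"%.{17 if precision is None else precision}g"
    with Path(path).open("w", encoding="utf-8") as fh:
        if header:
            fh.write(f"{len(space)} {space.k}\n")
        for tok, vec in zip(space.vocabulary, space.vectors):
            fh.write(tok + " " + " ".join(fmt % v for v in vec) + "\n")


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity of two nonzero vectors, in [-1, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors have different dimensionality")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("undefined cosine: zero vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def vector_length(v: np.ndarray) -> float:
    """Euclidean norm of a word vector."""
    return float(np.linalg.norm(np.asarray(v, dtype=float)))
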