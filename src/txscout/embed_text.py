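"""Text embedding: a pluggable embedder contract with a deterministic fallback.

Every embedder maps text to a fixed-length, L2-normalized vector (all-zero for
empty text). Retrieval code depends only on this contract, so the default
hashing embedder can be swapped for a pretrained sentence-transformer without
touching any interface.

The fallback is a signed bag-of-words feature hasher: text is lowercased and
split on non-alphanumerics; each token is placed into one of ``dim`` buckets
by a 64-bit FNV-1a hash, with a +/-1 sign taken from a second FNV-1a pass over
the token plus a sign-salt byte; bucket counts are accumulated and
L2-normalized. FNV-1a is fixed by its offset/prime constants, so the vectors
are identical across processes and operating systems (no hash randomization,
no seed).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Protocol, runtime_checkable

import numpy as np

from .corpus import Corpus, EmbeddingDB, assemble_study_text

__all__ = [
    "DEFAULT_TEXT_DIM",
    "EmbeddingError",
    "HashingTextEmbedder",
    "SentenceTransformerEmbedder",
    "TextEmbedder",
    "build_metadata_db",
    "embed_query",
    "get_embedder",
    "hash_embed",
]

DEFAULT_TEXT_DIM = 384

_FNV_OFFSET = 0xCBF29CE484222325
_FNV_PRIME = 0x100000001B3
_MASK64 = (1 << 64) - 1
_SIGN_SALT = b"\x00s"

_TOKEN_RE = re.compile(r"[a-z0-9]+")


class EmbeddingError(RuntimeError):
    """Raised when an embedder fails on a specific input."""


@runtime_checkable
class TextEmbedder(Protocol):
    """Contract: name, output dimension, and a text -> unit vector map."""

    name: str
    dim: int

    def embed(self, text: str) -> np.ndarray: ...


def _fnv1a(data: bytes) -> int:
    h = _FNV_OFFSET
    for byte in data:
        h = ((h ^ byte) * _FNV_PRIME) & _MASK64
    return h


def _tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text.lower())


def hash_embed(text: str, dim: int = DEFAULT_TEXT_DIM) -> np.ndarray:
    """Signed feature-hashing embedding of *text* into ``dim`` buckets.

    Deterministic across processes; empty or token-free text maps to the zero
    vector, anything else to a unit vector.
    """
    if dim < 1:
        raise ValueError(f"dim must be >= 1, got {dim}")
    vec = np.zeros(dim, dtype=np.float64)
    for token in _tokenize(text):
        data = token.encode("utf-8")
        bucket = _fnv1a(data) % dim
        sign = 1.0 if _fnv1a(data + _SIGN_SALT) & 1 else -1.0
        vec[bucket] += sign
    norm = np.linalg.norm(vec)
    if norm > 0:
        vec /= norm
    return vec


@dataclass(frozen=True)
class HashingTextEmbedder:
    """Deterministic FNV-1a feature-hashing embedder (see :func:`hash_embed`)."""

    dim: int = DEFAULT_TEXT_DIM
    name: str = "hash"

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError(f"dim must be >= 1, got {self.dim}")

    def embed(self, text: str) -> np.ndarray:
        return hash_embed(text, self.dim)

    def embed_many(self, texts: Iterable[str]) -> np.ndarray:
        rows = [self.embed(t) for t in texts]
        if not rows:
            return np.zeros((0, self.dim), dtype=np.float64)
        return np.vstack(rows)


class SentenceTransformerEmbedder:
    """Adapter for a pretrained sentence-embedding model (lazy import).

    Requires the optional ``sentence-transformers`` dependency; the model is
    loaded on first use. Output vectors are L2-normalized to satisfy the
    embedder contract.
    """

    def __init__(self, model_name: str = "all-MiniLM-L6-v2"):
        self.name = model_name
        self._model = None
        self.dim = DEFAULT_TEXT_DIM  # refined after the model loads

    def _load(self):
        if self._model is None:
            try:
                from sentence_transformers import SentenceTransformer
            except ImportError as exc:  # pragma: no cover - optional extra
                raise EmbeddingError(
                    "sentence-transformers is not installed; install the 'lm' "
                    "extra or use the 'hash' embedder"
                ) from exc
            self._model = SentenceTransformer(self.name)
            self.dim = int(self._model.get_sentence_embedding_dimension())
        return self._model

    def embed(self, text: str) -> np.ndarray:  # pragma: no cover - optional extra
        if not text.strip():
            self._load()
            return np.zeros(self.dim, dtype=np.float64)
        vec = np.asarray(self._load().encode([text])[0], dtype=np.float64)
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec


_REGISTRY = {
    "hash": HashingTextEmbedder,
    "sentence-transformer": SentenceTransformerEmbedder,
}


def get_embedder(name: str, **kwargs) -> TextEmbedder:
    """Instantiate a registered embedder by name (``hash`` or ``sentence-transformer``)."""
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown embedder {name!r}; available: {sorted(_REGISTRY)}"
        ) from None
    return factory(**kwargs)


def build_metadata_db(corpus: Corpus, embedder: TextEmbedder | None = None) -> EmbeddingDB:
    """Embed each study's assembled text into one row of a metadata database.

    Rows follow corpus study order; ids are study accessions.
    """
    if embedder is None:
        embedder = HashingTextEmbedder()
    rows = []
    for study in corpus.studies:
        try:
            rows.append(embedder.embed(assemble_study_text(study)))
        except Exception as exc:
            raise EmbeddingError(
                f"embedder {embedder.name!r} failed on study {study.study_id}: {exc}"
            ) from exc
    vectors = np.vstack(rows) if rows else np.zeros((0, embedder.dim))
    return EmbeddingDB(
        ids=[s.study_id for s in corpus.studies],
        vectors=vectors,
        meta={"kind": "metadata", "embedder": embedder.name, "dim": int(embedder.dim)},
    )


def embed_query(text: str, embedder: TextEmbedder | None = None) -> np.ndarray:
    """Embed a free-text query with the same embedder used for the database."""
    if embedder is None:
        embedder = HashingTextEmbedder()
    return embedder.embed(text)
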