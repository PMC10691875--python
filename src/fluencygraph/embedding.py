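"""Fixed-length sequence representations and the participant similarity graph.

Whole word sequences are embedded by a pluggable backend. The default,
:class:`HashingEmbedder`, is a deterministic local feature-hashing model: the
tokens are joined with ``", "``, character n-grams (n = 2..4) and adjacent
word bigrams are extracted, each feature is hashed to one of ``d`` signed
buckets with a seeded keyed hash, and the resulting count vector is
L2-normalized. It is order-sensitive (via the word bigrams and cross-token
character n-grams) and self-contained; an adapter for a hosted
large-language-model embedding service is provided as an interface stub only.

Pairwise cosine similarities between the (unit-norm) rows form a complete
weighted participant graph; per-edge absolute age and NART differences are
attached as edge covariates and per-node mean transformed word frequency as
a node covariate.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .cohort import Participant
from .lexicon import FrequencyLexicon, MISSING
from .scoring import Transcript

__all__ = [
    "EmbeddingMatrix",
    "HashingEmbedder",
    "ExternalEmbeddingAdapter",
    "SimilarityGraph",
    "embed_sequences",
    "cosine_adjacency",
    "attach_covariates",
    "node_mean_frequency",
]

JOIN_DELIMITER = ", "


@dataclass
class EmbeddingMatrix:
    """L2-normalized n x d sequence representations."""

    participant_ids: list[str]
    vectors: np.ndarray
    backend_tag: str

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.participant_ids):
            raise ValueError("vectors must be an (n_participants, d) matrix")
        norms = np.linalg.norm(self.vectors, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("embedding rows must be L2-normalized")

    @property
    def d(self) -> int:
        return self.vectors.shape[1]


class HashingEmbedder:
    """Deterministic local feature-hashing sequence embedder."""

    name = "local-hash"

    def __init__(self, d: int = 2048, seed: int = 0):
        if d < 16:
            raise ValueError("embedding dimension must be >= 16")
        self.d = d
        self.seed = seed
        self._key = int(seed).to_bytes(8, "little", signed=True)

    def _features(self, tokens: Sequence[str]) -> Iterable[str]:
        text = JOIN_DELIMITER.join(tokens)
        for n in (2, 3, 4):
            for i in range(len(text) - n + 1):
                yield f"c{n}:{text[i:i + n]}"
        for a, b in zip(tokens, tokens[1:]):
            yield f"bg:{a} {b}"

    def embed_one(self, tokens: Sequence[str]) -> np.ndarray:
        v = np.zeros(self.d)
        for feat in self._features(tokens):
            h = int.from_bytes(
                hashlib.blake2b(feat.encode(), key=self._key, digest_size=8).digest(),
                "little",
            )
            sign = 1.0 if h & 1 else -1.0
            v[(h >> 1) % self.d] += sign
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError("sequence produced an all-zero embedding")
        return v / norm

    def embed(self, token_lists: Sequence[Sequence[str]]) -> np.ndarray:
        return np.stack([self.embed_one(toks) for toks in token_lists])


class ExternalEmbeddingAdapter:
    """Interface stub for a hosted embedding service.

    Construct with the target engine name, dimensionality and a callable
    ``request_fn(list_of_texts) -> list_of_vectors``; the package never
    supplies such a callable itself and the test suite never invokes one.
    """

    def __init__(self, name: str, d: int,
                 request_fn: Optional[Callable[[list[str]], list[list[float]]]] = None):
        self.name = name
        self.d = d
        self._request_fn = request_fn

    def embed(self, token_lists: Sequence[Sequence[str]]) -> np.ndarray:
        if self._request_fn is None:
            raise RuntimeError(
                f"external embedding backend {self.name!r} is not configured"
            )
        texts = [JOIN_DELIMITER.join(toks) for toks in token_lists]
        vecs = np.asarray(self._request_fn(texts), dtype=float)
        return vecs / np.linalg.norm(vecs, axis=1, keepdims=True)


def embed_sequences(
    transcripts: Sequence[Transcript],
    backend: object | None = None,
    d: int = 2048,
    seed: int = 0,
) -> EmbeddingMatrix:
    """Embed every transcript into a fixed-length unit vector."""
    if not transcripts:
        raise ValueError("no transcripts to embed")
    if backend is None:
        backend = HashingEmbedder(d=d, seed=seed)
    vectors = backend.embed([t.tokens for t in transcripts])
    return EmbeddingMatrix(
        participant_ids=[t.participant_id for t in transcripts],
        vectors=vectors,
        backend_tag=getattr(backend, "name", type(backend).__name__),
    )


@dataclass
class SimilarityGraph:
    """Complete weighted participant graph.

    ``weights`` is the symmetric cosine-similarity matrix with zero diagonal
    (self-loops excluded); ``edge_covariates`` maps covariate name to a
    symmetric per-edge matrix; ``node_covariates`` maps name to a per-node
    vector. ``sparsification_k`` records optional mutual k-NN sparsification
    (an edge is kept when it is in either endpoint's top-k).
    """

    participant_ids: list[str]
    weights: np.ndarray
    edge_covariates: dict[str, np.ndarray] = field(default_factory=dict)
    node_covariates: dict[str, np.ndarray] = field(default_factory=dict)
    sparsification_k: Optional[int] = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        n = len(self.participant_ids)
        if w.shape != (n, n):
            raise ValueError("weight matrix shape mismatch")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.abs(w) > 1 + 1e-9):
            raise ValueError("cosine weights must lie in [-1, 1]")
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n(self) -> int:
        return len(self.participant_ids)


def cosine_adjacency(E: EmbeddingMatrix,
                     sparsification_k: Optional[int] = None) -> SimilarityGraph:
    """Pairwise cosine similarity of embedding rows as a weighted graph."""
    if E.vectors.shape[0] < 2:
        raise ValueError("need at least two participants")
    norms = np.linalg.norm(E.vectors, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm embedding row")
    W = E.vectors @ E.vectors.T
    np.fill_diagonal(W, 0.0)
    W = np.clip((W + W.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(W, 0.0)
    if sparsification_k is not None:
        n = W.shape[0]
        k = min(sparsification_k, n - 1)
        keep = np.zeros_like(W, dtype=bool)
        ranked = W - np.diag(np.full(n, np.inf))  # self-edges never ranked
        order = np.argsort(-ranked, axis=1)
        rows = np.repeat(np.arange(n), k)
        cols = order[:, :k].ravel()
        keep[rows, cols] = True
        keep |= keep.T  # mutualized: kept if in either endpoint's top-k
        W = np.where(keep, W, 0.0)
    return SimilarityGraph(list(E.participant_ids), W,
                           sparsification_k=sparsification_k)


def node_mean_frequency(t: Transcript, lexicon: FrequencyLexicon) -> float:
    """Mean transformed frequency over the tokens found in the lexicon."""
    vals = [lexicon.transformed(tok) for tok in t.tokens]
    vals = [v for v in vals if not math.isnan(v)]
    if not vals:
        return MISSING
    return sum(vals) / len(vals)


def attach_covariates(
    G: SimilarityGraph,
    participants: Sequence[Participant],
    transcripts: Optional[Sequence[Transcript]] = None,
    lexicon: Optional[FrequencyLexicon] = None,
) -> SimilarityGraph:
    """Attach age/NART edge covariates (absolute differences) and, when a
    lexicon is given, per-node mean word frequency. Order must match."""
    by_id = {p.participant_id: p for p in participants}
    if set(G.participant_ids) - set(by_id):
        raise ValueError("participants missing for some graph nodes")
    age = np.array([by_id[i].age for i in G.participant_ids])
    nart = np.array([by_id[i].nart for i in G.participant_ids])
    G.edge_covariates["d_age"] = np.abs(age[:, None] - age[None, :])
    G.edge_covariates["d_nart"] = np.abs(nart[:, None] - nart[None, :])
    G.node_covariates["age"] = age
    G.node_covariates["nart"] = nart
    if transcripts is not None and lexicon is not None:
        by_tid = {t.participant_id: t for t in transcripts}
        G.node_covariates["mean_word_frequency"] = np.array(
            [node_mean_frequency(by_tid[i], lexicon) for i in G.participant_ids]
        )
    return G
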