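"""Word and document embeddings and the interpretable document–word matrix.

Words from the learning corpus are embedded with skip-gram negative sampling
(SGNS); documents with the distributed bag-of-words paragraph vector
(PV-DBOW), here trained against the *frozen* word matrix so that a document
vector is optimised purely to score its own words highly.  The product

    DW = D · Wᵀ        (m documents × n vocabulary words)

is then an interpretable document-by-word feature matrix: entry (j, i) is the
affinity of document j for word i, and any linear (analogy) structure among
word vectors transfers to the columns of DW.  Because document vectors are
fitted per document with the word matrix frozen, embedding unseen (test)
documents is the very same procedure and leaks nothing back into W.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .corpus import Corpus

__all__ = [
    "Vocabulary",
    "EmbeddingConfig",
    "WordMatrix",
    "DocMatrix",
    "DocWordMatrix",
    "build_vocabulary",
    "train_word_embeddings",
    "train_doc_embeddings",
    "infer_doc_vectors",
    "compute_dw",
    "trim_columns",
]


class EmbeddingError(ValueError):
    pass


@dataclass(frozen=True)
class EmbeddingConfig:
    """Hyperparameters shared by SGNS and PV-DBOW.

    Defaults follow common practice for small clinical corpora: dimension
    300 and 5 negative samples, vocabulary capped at the top 1000 words;
    window 5, 20 epochs, initial learning rate 0.025 decaying linearly.
    """

    k: int = 300
    negatives: int = 5
    top_k: int = 1000
    epochs: int = 20
    context_window: int = 5
    seed: int = 0
    min_count: int = 1
    lr: float = 0.025
    lr_min: float = 1e-4
    noise_power: float = 0.75
    doc_epochs: int | None = None  # PV-DBOW passes per document; None = epochs

    def __post_init__(self) -> None:
        if self.k < 1 or self.negatives < 1 or self.top_k < 1:
            raise EmbeddingError("k, negatives and top_k must all be >= 1")


@dataclass(frozen=True)
class Vocabulary:
    """Top-k corpus words ordered by descending frequency, ties broken
    lexicographically."""

    words: tuple[str, ...]
    frequency: dict[str, int]
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            object.__setattr__(self, "index", {w: i for i, w in enumerate(self.words)})

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self.index


@dataclass
class WordMatrix:
    W: np.ndarray  # (n, k)
    vocabulary: Vocabulary

    def __post_init__(self) -> None:
        if self.W.shape[0] != len(self.vocabulary):
            raise EmbeddingError("W rows must align with vocabulary")
        if not np.all(np.isfinite(self.W)):
            raise EmbeddingError("W contains non-finite entries")


@dataclass
class DocMatrix:
    D: np.ndarray  # (m, k)
    doc_ids: tuple[str, ...]
    degenerate: np.ndarray = None  # bool mask: no in-vocabulary tokens

    def __post_init__(self) -> None:
        if self.D.shape[0] != len(self.doc_ids):
            raise EmbeddingError("D rows must align with doc_ids")
        if self.degenerate is None:
            self.degenerate = np.zeros(self.D.shape[0], dtype=bool)
        if not np.all(np.isfinite(self.D)):
            raise EmbeddingError("D contains non-finite entries")


@dataclass
class DocWordMatrix:
    DW: np.ndarray  # (m, n)
    doc_ids: tuple[str, ...]
    vocabulary: Vocabulary
    degenerate: np.ndarray = None

    def __post_init__(self) -> None:
        if self.degenerate is None:
            self.degenerate = np.zeros(self.DW.shape[0], dtype=bool)

    @property
    def words(self) -> tuple[str, ...]:
        return tuple(self.vocabulary.words)


def record_id(rec) -> str:
    return f"{rec.patient_id}|{rec.date.isoformat()}"


def build_vocabulary(corpus: Corpus, top_k: int = 1000, min_count: int = 1) -> Vocabulary:
    """Top ``top_k`` most frequent tokens by total corpus count."""
    counts: Counter[str] = Counter()
    for rec in corpus.records:
        counts.update(rec.tokens)
    if not counts:
        raise EmbeddingError("cannot build a vocabulary from an empty corpus")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    kept = [(w, c) for w, c in ranked[:top_k] if c >= min_count]
    return Vocabulary(words=tuple(w for w, _ in kept), frequency=dict(kept))


def _index_records(corpus: Corpus, vocab: Vocabulary):
    """Flatten records to in-vocabulary token-id streams with offsets."""
    ids: list[int] = []
    offsets = [0]
    doc_ids = []
    for rec in corpus.records:
        ids.extend(vocab.index[t] for t in rec.tokens if t in vocab.index)
        offsets.append(len(ids))
        doc_ids.append(record_id(rec))
    return (
        np.asarray(ids, dtype=np.int32),
        np.asarray(offsets, dtype=np.int64),
        tuple(doc_ids),
    )


def _noise_cumulative(vocab: Vocabulary, power: float) -> np.ndarray:
    freq = np.array([vocab.frequency[w] for w in vocab.words], dtype=np.float64)
    probs = freq**power
    probs /= probs.sum()
    return np.cumsum(probs)


def train_word_embeddings(corpus: Corpus, vocab: Vocabulary, cfg: EmbeddingConfig) -> WordMatrix:
    """Train SGNS word vectors on in-vocabulary tokens; deterministic for a
    given seed (single worker)."""
    if len(vocab) == 0:
        raise EmbeddingError("vocabulary is empty")
    data, offsets, _ = _index_records(corpus, vocab)
    if len(data) == 0:
        raise EmbeddingError("no in-vocabulary tokens to train on")
    n, k = len(vocab), cfg.k
    rng = np.random.default_rng(cfg.seed)
    w_in = ((rng.random((n, k)) - 0.5) / k).astype(np.float32)
    w_out = np.zeros((n, k), dtype=np.float32)
    _kernels.sgns_train(
        data, offsets, w_in, w_out,
        _noise_cumulative(vocab, cfg.noise_power),
        cfg.context_window, cfg.negatives, cfg.lr, cfg.lr_min, cfg.epochs,
        np.uint64(cfg.seed),
    )
    return WordMatrix(W=w_in, vocabulary=vocab)


def _fit_doc_vectors(corpus: Corpus, vocab: Vocabulary, W: WordMatrix, cfg: EmbeddingConfig, seed: int) -> DocMatrix:
    data, offsets, doc_ids = _index_records(corpus, vocab)
    m = len(doc_ids)
    d_mat = np.zeros((m, cfg.k), dtype=np.float32)
    _kernels.dbow_fit_docs(
        data, offsets, W.W, d_mat,
        _noise_cumulative(vocab, cfg.noise_power),
        cfg.negatives, cfg.lr, cfg.lr_min,
        cfg.epochs if cfg.doc_epochs is None else cfg.doc_epochs,
        np.uint64(seed),
    )
    degenerate = np.diff(offsets) == 0
    return DocMatrix(D=d_mat, doc_ids=doc_ids, degenerate=degenerate)


def train_embeddings(corpus: Corpus, vocab: Vocabulary, cfg: EmbeddingConfig) -> tuple[WordMatrix, DocMatrix]:
    """Train W by SGNS, then fit PV-DBOW document vectors against it."""
    W = train_word_embeddings(corpus, vocab, cfg)
    return W, _fit_doc_vectors(corpus, vocab, W, cfg, cfg.seed)


def train_doc_embeddings(corpus: Corpus, vocab: Vocabulary, cfg: EmbeddingConfig) -> DocMatrix:
    """PV-DBOW document vectors for the learning corpus, trained against the
    frozen word matrix (each document fitted from its own seeded stream)."""
    return train_embeddings(corpus, vocab, cfg)[1]


def infer_doc_vectors(corpus: Corpus, vocab: Vocabulary, W: WordMatrix, cfg: EmbeddingConfig) -> DocMatrix:
    """Embed unseen documents with W and the noise distribution frozen.

    A document with zero in-vocabulary tokens keeps a zero vector and is
    flagged degenerate; downstream scoring maps it to probability 0.5.
    """
    if W.W.shape[1] != cfg.k:
        raise EmbeddingError(f"W has dimension {W.W.shape[1]}, config says {cfg.k}")
    return _fit_doc_vectors(corpus, vocab, W, cfg, cfg.seed)


def compute_dw(D: DocMatrix, W: WordMatrix) -> DocWordMatrix:
    """DW = D · Wᵀ (documents × vocabulary words)."""
    if D.D.shape[1] != W.W.shape[1]:
        raise EmbeddingError(
            f"dimension mismatch: D is m×{D.D.shape[1]}, W is n×{W.W.shape[1]}"
        )
    dw = np.asarray(D.D, dtype=np.float64) @ np.asarray(W.W, dtype=np.float64).T
    return DocWordMatrix(
        DW=dw, doc_ids=D.doc_ids, vocabulary=W.vocabulary, degenerate=D.degenerate.copy()
    )


def trim_columns(dw: DocWordMatrix, keep: list[str]) -> DocWordMatrix:
    """Restrict DW to the columns of ``keep`` (order taken from ``keep``)."""
    if not keep:
        raise EmbeddingError("keep must name at least one word")
    unknown = [w for w in keep if w not in dw.vocabulary.index]
    if unknown:
        raise EmbeddingError(f"words not in vocabulary: {unknown[:5]}")
    cols = [dw.vocabulary.index[w] for w in keep]
    sub_vocab = Vocabulary(
        words=tuple(keep),
        frequency={w: dw.vocabulary.frequency[w] for w in keep},
    )
    return DocWordMatrix(
        DW=dw.DW[:, cols],
        doc_ids=dw.doc_ids,
        vocabulary=sub_vocab,
        degenerate=dw.degenerate.copy(),
    )
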