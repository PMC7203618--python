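import numpy as np
import pytest

from fallrisk.corpus import Corpus
from fallrisk.embedding import (
    DocMatrix,
    EmbeddingConfig,
    EmbeddingError,
    Vocabulary,
    WordMatrix,
    build_vocabulary,
    compute_dw,
    infer_doc_vectors,
    train_embeddings,
    train_word_embeddings,
    trim_columns,
)

from conftest import make_corpus, patient, record


def _vocab(words):
    return Vocabulary(words=tuple(words), frequency={w: 1 for w in words})


@pytest.fixture(scope="module")
def grammar_corpus():
    """Synthetic corpus where tokens x and y always share contexts (both
    appear between the same frame words) while z appears in disjoint
    frames — a distributional-similarity test bed."""
    rng = np.random.default_rng(42)
    pats = [patient(f"P{i}") for i in range(40)]
    recs = []
    for i in range(40):
        toks = []
        for _ in range(30):
            if rng.random() < 0.5:
                toks += ["frameA", "x" if rng.random() < 0.5 else "y", "frameB"]
            else:
                toks += ["frameC", "z", "frameD"]
        recs.append(record(f"P{i}", 1, tuple(toks)))
    return make_corpus(pats, recs)


class TestVocabulary:
    def test_frequency_ordering(self):
        c = make_corpus([patient("A")], [record("A", 1, ("a",) * 5 + ("b",) * 3 + ("c",))])
        v = build_vocabulary(c, top_k=2)
        assert v.words == ("a", "b")

    def test_top_k_above_distinct_keeps_all(self, tiny_corpus):
        v = build_vocabulary(tiny_corpus, top_k=1000)
        assert len(v) == len({t for r in tiny_corpus.records for t in r.tokens})

    def test_tie_break_matches_full_sort_oracle(self):
        tokens = ["m", "z", "a", "z", "m", "a", "q", "b"]
        c = make_corpus([patient("A")], [record("A", 1, tuple(tokens))])
        v = build_vocabulary(c, top_k=3)
        from collections import Counter

        oracle = [w for w, _ in sorted(Counter(tokens).items(), key=lambda kv: (-kv[1], kv[0]))][:3]
        assert list(v.words) == oracle

    def test_order_invariance(self, tiny_corpus):
        reversed_corpus = Corpus(
            patients=dict(tiny_corpus.patients), records=list(reversed(tiny_corpus.records))
        )
        assert build_vocabulary(tiny_corpus, 10).words == build_vocabulary(reversed_corpus, 10).words

    def test_empty_corpus_rejected(self):
        with pytest.raises(EmbeddingError):
            build_vocabulary(Corpus(patients={}, records=[]), top_k=5)


class TestComputeDW:
    def test_identity_scaled(self):
        D = DocMatrix(D=np.array([[1.0, 0.0], [0.0, 1.0]]), doc_ids=("d1", "d2"))
        W = WordMatrix(W=np.array([[2.0, 0.0], [0.0, 3.0]]), vocabulary=_vocab(["u", "v"]))
        dw = compute_dw(D, W)
        assert np.allclose(dw.DW, [[2.0, 0.0], [0.0, 3.0]])

    def test_direct_arithmetic(self):
        D = DocMatrix(D=np.array([[1.0, 2.0]]), doc_ids=("d",))
        W = WordMatrix(W=np.array([[3.0, -1.0]]), vocabulary=_vocab(["w"]))
        assert compute_dw(D, W).DW[0, 0] == pytest.approx(1.0)

    def test_brute_force_inner_products(self):
        rng = np.random.default_rng(0)
        for m, n, k in [(1, 1, 1), (3, 4, 2), (10, 10, 10)]:
            Dm = rng.standard_normal((m, k))
            Wm = rng.standard_normal((n, k))
            dw = compute_dw(
                DocMatrix(D=Dm, doc_ids=tuple(f"d{i}" for i in range(m))),
                WordMatrix(W=Wm, vocabulary=_vocab([f"w{i}" for i in range(n)])),
            )
            oracle = np.array([[Dm[j] @ Wm[i] for i in range(n)] for j in range(m)])
            assert np.allclose(dw.DW, oracle)

    def test_bilinearity(self):
        rng = np.random.default_rng(1)
        Dm = rng.standard_normal((4, 3))
        W1 = rng.standard_normal((5, 3))
        W2 = rng.standard_normal((5, 3))
        ids = tuple(f"d{i}" for i in range(4))
        vocab = _vocab([f"w{i}" for i in range(5)])
        f = lambda d, w: compute_dw(DocMatrix(D=d, doc_ids=ids), WordMatrix(W=w, vocabulary=vocab)).DW
        assert np.allclose(f(2.5 * Dm, W1), 2.5 * f(Dm, W1))
        assert np.allclose(f(Dm, W1 + W2), f(Dm, W1) + f(Dm, W2))

    def test_analogy_linearity_transfers_to_dw(self):
        # construct word vectors with w1 - w2 = w3 - w4 exactly
        rng = np.random.default_rng(2)
        w2, w4 = rng.standard_normal((2, 6))
        delta = rng.standard_normal(6)
        Wm = np.vstack([w2 + delta, w2, w4 + delta, w4])
        Dm = rng.standard_normal((7, 6))
        dw = compute_dw(
            DocMatrix(D=Dm, doc_ids=tuple(f"d{i}" for i in range(7))),
            WordMatrix(W=Wm, vocabulary=_vocab(["w1", "w2", "w3", "w4"])),
        )
        lhs = dw.DW[:, 0] - dw.DW[:, 1]
        rhs = dw.DW[:, 2] - dw.DW[:, 3]
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_dimension_mismatch(self):
        D = DocMatrix(D=np.zeros((2, 3)), doc_ids=("a", "b"))
        W = WordMatrix(W=np.zeros((2, 4)), vocabulary=_vocab(["u", "v"]))
        with pytest.raises(EmbeddingError, match="mismatch"):
            compute_dw(D, W)


class TestTrim:
    def _dw(self):
        rng = np.random.default_rng(3)
        Dm = rng.standard_normal((4, 3))
        Wm = rng.standard_normal((5, 3))
        vocab = _vocab([f"w{i}" for i in range(5)])
        return (
            compute_dw(DocMatrix(D=Dm, doc_ids=tuple("abcd")), WordMatrix(W=Wm, vocabulary=vocab)),
            Dm,
            Wm,
        )

    def test_full_vocabulary_is_identity(self):
        dw, _, _ = self._dw()
        out = trim_columns(dw, list(dw.words))
        assert np.array_equal(out.DW, dw.DW)

    def test_empty_keep_rejected(self):
        dw, _, _ = self._dw()
        with pytest.raises(EmbeddingError):
            trim_columns(dw, [])

    def test_unknown_word_rejected(self):
        dw, _, _ = self._dw()
        with pytest.raises(EmbeddingError, match="not in vocabulary"):
            trim_columns(dw, ["w0", "nope"])

    def test_commutes_with_compute_dw_on_kept_rows(self):
        dw, Dm, Wm = self._dw()
        keep = ["w3", "w1"]
        trimmed = trim_columns(dw, keep)
        direct = Dm @ Wm[[3, 1]].T
        assert np.allclose(trimmed.DW, direct)


class TestTraining:
    CFG = EmbeddingConfig(k=16, epochs=3, top_k=50, seed=9)

    def test_same_seed_identical_matrices(self, grammar_corpus):
        v = build_vocabulary(grammar_corpus, top_k=50)
        W1, D1 = train_embeddings(grammar_corpus, v, self.CFG)
        W2, D2 = train_embeddings(grammar_corpus, v, self.CFG)
        assert np.array_equal(W1.W, W2.W)
        assert np.array_equal(D1.D, D2.D)

    def test_output_shapes(self, grammar_corpus):
        v = build_vocabulary(grammar_corpus, top_k=50)
        W, D = train_embeddings(grammar_corpus, v, self.CFG)
        assert W.W.shape == (len(v), 16)
        assert D.D.shape == (grammar_corpus.n_records, 16)

    def test_default_dimension_is_300(self):
        assert EmbeddingConfig().k == 300 and EmbeddingConfig().negatives == 5

    def test_shared_contexts_embed_closer(self, grammar_corpus):
        v = build_vocabulary(grammar_corpus, top_k=50)
        W, _ = train_embeddings(grammar_corpus, v, EmbeddingConfig(k=16, epochs=10, top_k=50, seed=9))
        cos = lambda a, b: a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
        x, y, z = (W.W[v.index[t]] for t in ("x", "y", "z"))
        assert cos(x, y) > cos(x, z)

    def test_two_topic_documents_separate(self):
        rng = np.random.default_rng(5)
        pats = [patient(f"P{i}") for i in range(30)]
        recs = []
        for i in range(30):
            topic = ["cat", "dog", "pet"] if i % 2 == 0 else ["ion", "atom", "lab"]
            toks = tuple(rng.choice(topic, size=25))
            recs.append(record(f"P{i}", 1, toks))
        c = make_corpus(pats, recs)
        v = build_vocabulary(c, top_k=10)
        _, D = train_embeddings(c, v, EmbeddingConfig(k=12, epochs=20, top_k=10, seed=3))
        d0, d2, d1 = D.D[0], D.D[2], D.D[1]
        cos = lambda a, b: a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
        assert cos(d0, d2) > cos(d0, d1)

    def test_empty_vocabulary_rejected(self, grammar_corpus):
        with pytest.raises(EmbeddingError):
            train_word_embeddings(
                grammar_corpus, Vocabulary(words=(), frequency={}), self.CFG
            )


class TestInference:
    def test_degenerate_document_flagged(self, grammar_corpus):
        v = build_vocabulary(grammar_corpus, top_k=50)
        W, _ = train_embeddings(grammar_corpus, v, TestTraining.CFG)
        odd = make_corpus([patient("Q")], [record("Q", 1, ("unseen", "tokens"))])
        D = infer_doc_vectors(odd, v, W, TestTraining.CFG)
        assert D.degenerate.tolist() == [True]

    def test_same_seed_identical_inference(self, grammar_corpus):
        v = build_vocabulary(grammar_corpus, top_k=50)
        W, _ = train_embeddings(grammar_corpus, v, TestTraining.CFG)
        D1 = infer_doc_vectors(grammar_corpus, v, W, TestTraining.CFG)
        D2 = infer_doc_vectors(grammar_corpus, v, W, TestTraining.CFG)
        assert np.array_equal(D1.D, D2.D)

    def test_training_document_self_retrieval(self):
        # each document carries its own high-frequency marker token, so an
        # inferred vector's nearest training neighbour should be itself
        rng = np.random.default_rng(11)
        pats = [patient(f"P{i}") for i in range(20)]
        recs = []
        for i in range(20):
            toks = [f"marker{i:02d}"] * 12 + list(rng.choice(["bg1", "bg2", "bg3"], size=8))
            rng.shuffle(toks)
            recs.append(record(f"P{i}", 1, tuple(toks)))
        c = make_corpus(pats, recs)
        v = build_vocabulary(c, top_k=30)
        cfg = EmbeddingConfig(k=16, epochs=20, top_k=30, seed=9)
        W, D_train = train_embeddings(c, v, cfg)
        D_new = infer_doc_vectors(c, v, W, EmbeddingConfig(k=16, epochs=20, top_k=30, seed=77))
        nearest = np.argmax(D_new.D @ D_train.D.T, axis=1)
        assert (nearest == np.arange(20)).mean() >= 0.9
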