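"""Train word/document embeddings and inspect the document-word matrix.

Shows the core representation: skip-gram (SGNS) word vectors, PV-DBOW
document vectors fitted against the frozen word matrix, and the
interpretable product DW = D·Wᵀ whose entry (j, i) scores document j's
affinity for vocabulary word i.
"""

from dataclasses import replace

import numpy as np

from fallrisk import (
    EmbeddingConfig,
    build_vocabulary,
    compute_dw,
    generate_corpus,
    standard_benchmark,
    train_embeddings,
)

cfg = replace(
    standard_benchmark(),
    n_fallers=30, n_nonfallers=30, vocab_size=400,
    records_mean_faller=10, records_mean_nonfaller=10,
    seed=21,
)
corpus, truth = generate_corpus(cfg)

vocab = build_vocabulary(corpus, top_k=300)
emb = EmbeddingConfig(k=64, epochs=5, doc_epochs=15, top_k=300, seed=0)
W, D = train_embeddings(corpus, vocab, emb)
dw = compute_dw(D, W)

print(f"vocabulary: {len(vocab)} words;  W: {W.W.shape};  D: {D.D.shape};  DW: {dw.DW.shape}")

# a document's strongest DW columns should include words it actually contains
j = 0
rec = corpus.records[0]
top_cols = np.argsort(dw.DW[j])[::-1][:10]
top_words = [vocab.words[i] for i in top_cols]
present = [w for w in top_words if w in rec.tokens]
print(f"doc {dw.doc_ids[j]}: top-10 DW words {top_words}")
print(f"  of which {len(present)} occur in the document itself")
print()
print("DW rows act as smoothed word profiles of each document: the columns")
print("with the largest entries are dominated by words the document contains")
print("or words distributionally close to them.")
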