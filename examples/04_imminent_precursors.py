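"""Detect imminent (1-7 days pre-fall) precursor records among fallers.

The same modelling machinery runs at the record level: faller records are
tagged imminent / not-imminent by their distance to the next fall, and the
classifier is evaluated per record without patient aggregation.
"""

from dataclasses import replace

from fallrisk import (
    EmbeddingConfig,
    PipelineConfig,
    generate_corpus,
    run_imminent_experiment,
    standard_benchmark,
)
from fallrisk.corpus import FALLER

gen = replace(
    standard_benchmark(),
    n_fallers=120, n_nonfallers=10, vocab_size=800,
    records_mean_faller=30,
    seed=41,
)
corpus, truth = generate_corpus(gen)
fallers = corpus.subset([p for p, q in corpus.patients.items() if q.label == FALLER])

cfg = PipelineConfig(embedding=EmbeddingConfig(k=96, epochs=5, doc_epochs=15, top_k=600, seed=0))
report = run_imminent_experiment(fallers, cfg, seed=1, window_days=7, stratum="all")

prec = set(truth.precursor_tokens)
sel = set(report.selected_vocabulary)
print(f"record-level AUC {report.auc:.3f} over {len(report.scores)} test records")
print(f"selected vocabulary: {len(sel)} words "
      f"({len(sel & prec)}/{len(prec)} planted precursor tokens)")
print()
print("An AUC above 0.5 means the text written in the week before a fall is")
print("distinguishable from the faller's other records — the basis for a")
print("daily risk-monitoring alert.")
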