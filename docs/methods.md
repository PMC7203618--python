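# Methods

## Model and pipeline

`fallrisk` treats fall prediction as a case-control text-classification
problem. The analysis unit is the *nursing record*: all notes written for
one patient on one day, integrated into a single token sequence. Records
with 50 or fewer content characters are excluded before vectorisation (for
raw text, content characters are non-whitespace characters; for
pre-tokenized records, the sum of token lengths — a script-agnostic proxy
for the original Japanese/Chinese character count).

### Embeddings and the DW matrix

Words are embedded by skip-gram with negative sampling (SGNS). The
vocabulary is capped at the `top_k` most frequent words (default 1000),
frequency ties broken lexicographically; "most frequent" means total token
count, not document frequency. Noise words are drawn from the unigram
distribution raised to 0.75. The SGNS kernel is single-threaded with an
explicit splitmix64 stream, so a seed fully determines the result.

Document vectors use the distributed bag-of-words paragraph vector
(PV-DBOW) with one deliberate design choice: the word (output) matrix is
**frozen** during document fitting, and each document vector is optimised
independently against it from its own seeded stream. Consequences:

* training documents and unseen test documents go through the *identical*
  procedure, so test-time inference is well defined and cannot leak
  information back into the word matrix;
* `DW = D · Wᵀ` has a direct reading — entry (j, i) is document j's
  fitted affinity for word i (approximately its log-odds of occurrence
  under the document's softened unigram model).

Per-document RNG streams are decorrelated by passing the raw
(seed, doc-index) state through the splitmix64 mixer once. This matters:
raw consecutive splitmix states generate shifted copies of one sequence,
which would correlate neighbouring documents' random components — and since
corpora list fallers first, that artifact would encode the class label into
the embeddings at both train and test time.

A document with zero in-vocabulary tokens keeps a zero vector, is flagged
degenerate, and receives the neutral risk probability 0.5 downstream.

Defaults: dimension k = 300, negatives = 5, context window 5, 20 SGNS
epochs, initial learning rate 0.025 decaying linearly to 1e-4.
`doc_epochs` controls PV-DBOW passes per document separately (documents are
short, so they benefit from more passes than the word model needs).

### Risk model

Record label 1 = faller (or imminent), 0 = nonfaller (not imminent).
Features are the DW columns, standardized per column with learning-set
statistics (stored in the model and applied unchanged to test rows), so the
unit-scale prior is meaningful. Class imbalance is corrected *after*
standardization by SMOTE: synthetic minority rows are convex combinations
of a minority row and one of its 5 nearest minority neighbours, up to exact
balance.

The classifier is logistic regression with independent Normal(0, σ²)
priors on the intercept and coefficients (σ = 1 by default). Posteriors
are sampled with Hamiltonian Monte Carlo preconditioned by the Laplace
approximation: L-BFGS finds the mode, the Hessian there is
Cholesky-factored, and HMC runs in the whitened space (6 leapfrog steps,
step size tuned by dual averaging to 0.8 acceptance, with ±20% step
jitter to break resonances). Two chains of 500 post-warm-up draws each are
kept; convergence requires split-chain R̂ < 1.05 on every coordinate, and
the point estimate is the posterior mean. For a log-concave logistic
posterior this preconditioned sampler mixes essentially like independent
draws at a fraction of the cost of a general-purpose sampler.

### Vocabulary selection: why marginal significance

The learning patients are bisected at random three times (class-stratified),
giving six primary models. Within each, every word is tested for a
significant association with the outcome, and words significant in at least
4 of 6 models are selected.

The test is each word's **marginal** Bayesian association: a univariate
logistic regression (intercept + that word's DW column) with the same
normal prior, fitted by Newton iteration, with a Laplace posterior for the
slope; the word is significant when the 95% equal-tailed credible interval
excludes zero. All 1000 univariate fits are vectorised, so a primary model
costs a few matrix passes.

The alternative — testing each *coordinate* of the joint 1000-column fit —
cannot work here, for a structural reason: DW has rank at most the
embedding dimension k, so with n ≫ k columns each joint coordinate's
posterior is dominated by its prior (measured marginal sd ≈ 0.95 σ at
k=100/n=1000) while posterior means spread thinly across correlated
columns; no coordinate interval ever excludes zero, at any prior scale.
`run_bisection_ensemble(..., method="joint")` retains the joint-coordinate
rule for configurations where the feature count does not exceed the
embedding rank, and `significant_words()` applies the credible-interval
rule to any fitted joint model.

The final model is the joint Bayesian logistic fit (by MCMC, as above) on
the full learning set restricted to the selected columns. If no word
reaches the tally threshold — the expected outcome on a signal-free corpus
— the pipeline falls back to the uninformative model that scores every
record 0.5, rather than failing.

### Evaluation

Patient risk score = arithmetic mean of the patient's record
probabilities. The ROC curve scans all distinct cutoffs (score ≥ cutoff ⇒
predicted risk; ties step simultaneously); AUC is the trapezoidal area.
The operating threshold is the ROC point closest to (0, 1) in Euclidean
distance, ties broken to the lower cutoff. From the confusion matrix:
sensitivity tp/(tp+fn) and specificity tn/(tn+fp) with Wilson 95% CIs
(Wald available), odds ratio (tp·tn)/(fp·fn) with the Woolf log-interval
exp(ln OR ± 1.96·√(1/tp+1/fp+1/fn+1/tn)); any zero cell triggers the
Haldane–Anscombe +0.5 correction, flagged on the report. Cross-run
reproducibility is the R² of an OLS regression of one run's patient scores
on another's, computed on the intersection of the two runs' scored units
(replicates re-split the patients, so test sets differ). Summaries across
replicates are mean and sample SD (n−1).

The imminent-precursor analysis tags a faller's record *imminent* when its
date lies 1–7 days before any of the patient's falls (the fall day itself
excluded by default; a flag includes it). Evaluation is at the record
level — the probability that each held-out faller record is imminent —
with no patient aggregation, optionally restricted to long-stay (>60
records) or short-stay (≤45) fallers.

## Synthetic data

The generator emulates the statistical structure of a nursing-record
corpus, not its language. Background vocabulary frequencies follow a Zipf
law (exponent 1.0, 2000 words) so the top-1000 cap bites as it would on
natural text. Planted tokens are assigned a base probability of 0.003 —
the frequency of roughly the 40th-ranked background word — because the
discriminative words in real nursing notes (mobility, medication,
excretion terms) are common words, not rare ones. Risk tokens are
multiplied by e^effect in faller records, protective tokens by e^−effect;
precursor tokens are boosted ×3 inside the 7-day pre-fall window.
Record counts per patient are negative binomial (fallers mean 50,
nonfallers mean 30, dispersion 4), reproducing the roughly 2:1 record-count
imbalance of real faller/nonfaller cohorts; records are daily and
consecutive; ~80 tokens per record, with 5% of records drawn very short to
exercise the exclusion filter. Fall dates (one plus a Poisson(0.3) extra)
are placed uniformly in the record span.

The *null corpus* zeroes every class effect: token distributions are
identical across classes, the precursor boost is off, **and both classes
share the nonfaller record-count distribution** — "labels carry no signal"
is taken literally, so any downstream separation is a pipeline artifact.

What the generator does not emulate: topical structure (one shared
background distribution rather than multiple latent topics), SOAP note
structure, morphology, temporal drift within a stay. A consequence of the
single risk axis is that many background words correlate with it through
the document vectors, so the ensemble selects a liberal vocabulary
(~700–850 of 1000 words on the signal benchmark); the planted tokens are
recovered within it, which is what the recovery tests assert. Passing
benchmarks therefore demonstrate that the pipeline recovers planted
class-conditional frequency signal at realistic corpus sizes — not that it
would achieve any particular AUC on real clinical text.

## Benchmark problem sizes

The standard benchmark runs 150 fallers / 200 nonfallers (≈13,000 records,
≈1M tokens). For these experiments the pipeline uses embedding dimension
200, 6 SGNS epochs and 20 PV-DBOW passes — sizes chosen so a full
replicate (embeddings, six-model ensemble, final MCMC fit, held-out
scoring) completes in about two minutes on one CPU while leaving the
benchmark properties comfortably above their thresholds. The study-scale
defaults (k = 300, 20 epochs) remain the `EmbeddingConfig` defaults.

## Known limitations

* The marginal selection test inherits the usual caveat of marginal
  screens: words correlated with a true risk word are selected alongside it.
  The 4-of-6 stability vote and the joint final fit mitigate but do not
  remove this.
* Null-corpus AUC has substantial per-seed variance (±0.06): with at most a
  handful of noise words selected, patient scores are driven by a few noisy
  columns, and the test set holds only ~175 patients.
* The published proportion CIs could not be reproduced by Wald or Wilson
  intervals at the stated denominators; proportion CIs here are Wilson and
  are not claimed to match the published ones. The Woolf odds-ratio
  interval does reproduce the published values exactly.
* Convergence flags (R̂) are recorded per fit; non-convergence warns and
  flags rather than aborts, and the CLI exits 3 when a final model is
  flagged.
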