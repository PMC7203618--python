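"""Bayesian logistic risk modelling on document–word features.

The record-level classifier is a logistic regression fitted by MCMC with a
Normal(0, prior_sd²) prior on every weight.  Vocabulary selection follows a
stability-ensemble scheme: the learning set is randomly bisected at the
patient level three times, six models are fitted on the six halves (after
minority oversampling), and a word enters the "significant vocabulary" when
its posterior 95% credible interval excludes zero in at least four of the
six primary models.  The final model is refitted on the full learning set
restricted to the selected columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit
from sklearn.neighbors import NearestNeighbors

from .corpus import Corpus, FALLER, IMMINENT, SplitSpec, split_patients
from .embedding import (
    DocWordMatrix,
    EmbeddingConfig,
    build_vocabulary,
    compute_dw,
    train_embeddings,
    trim_columns,
)
from .mcmc import PosteriorFit, SamplerConfig, sample_logistic_posterior


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class OversampleConfig:
    k_neighbors: int = 5
    seed: int = 0


@dataclass(frozen=True)
class Scaler:
    """Per-column z-score parameters estimated on the learning set and
    applied unchanged to test rows.  Constant columns get unit scale."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Scaler":
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        return cls(mean=mean, sd=sd)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=np.float64) - self.mean) / self.sd


@dataclass
class LogisticRiskModel:
    """Fitted record-level risk model.

    ``weights`` are posterior means on the standardized feature scale,
    aligned with ``vocabulary``.  Risk probability of a feature row d is
    sigmoid(intercept + d_std · weights).
    """

    vocabulary: tuple[str, ...]
    intercept: float
    weights: np.ndarray
    posterior: PosteriorFit
    prior_sd: float
    scaler: Scaler
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.vocabulary):
            raise ModelError("one weight per vocabulary word required")

    @property
    def converged(self) -> bool:
        return self.posterior.converged


@dataclass
class SignificanceTally:
    """Per-word count of primary models (0..n_models) in which the word's
    weight was significant."""

    words: tuple[str, ...]
    counts: dict[str, int]
    n_models: int
    threshold: int = 4

    def __post_init__(self) -> None:
        bad = [w for w, c in self.counts.items() if not 0 <= c <= self.n_models]
        if bad:
            raise ModelError(f"counts out of range for {bad[:5]}")


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end settings for the modelling stages.

    ``target`` selects the classification label attached to each record:
    ``"label"`` for faller/nonfaller prediction, ``"imminent"`` for the
    pre-fall precursor analysis.
    """

    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    prior_sd: float = 1.0
    smote_k: int = 5
    bisections: int = 3
    min_models: int = 4
    level: float = 0.95
    split_fraction: float = 0.5
    min_chars: int = 50
    stratified_split: bool = True
    target: str = "label"


def benchmark_pipeline() -> PipelineConfig:
    """Pipeline settings used for the synthetic benchmark experiments:
    vocabulary capped at the top 1000 words as in the clinical study, with
    embedding sizes scaled to the benchmark corpus (dimension 200, 6 SGNS
    epochs, 20 PV-DBOW passes per document)."""
    return PipelineConfig(
        embedding=EmbeddingConfig(k=200, epochs=6, doc_epochs=20, top_k=1000, seed=0)
    )


def record_labels(corpus: Corpus, target: str = "label") -> np.ndarray:
    """0/1 label per record, in corpus record order."""
    if target == "label":
        return np.array(
            [1.0 if corpus.patients[r.patient_id].label == FALLER else 0.0 for r in corpus.records]
        )
    if target == "imminent":
        return np.array([1.0 if r.imminent == IMMINENT else 0.0 for r in corpus.records])
    raise ModelError(f"unknown target {target!r}")


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------

def oversample_minority(
    X: np.ndarray, y: np.ndarray, cfg: OversampleConfig = OversampleConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling to exact class balance.

    Each synthetic row is a convex combination of a random minority row and
    one of its ``k_neighbors`` nearest minority neighbours; original rows are
    always retained.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).ravel()
    values, counts = np.unique(y, return_counts=True)
    if len(values) < 2:
        raise ModelError("oversampling requires both classes present")
    if len(values) > 2:
        raise ModelError("binary labels required")
    if counts[0] == counts[1]:
        return X.copy(), y.copy()
    minority = values[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min <= cfg.k_neighbors:
        raise ModelError(
            f"minority class has {n_min} rows, not enough for k_neighbors="
            f"{cfg.k_neighbors}; use a smaller k"
        )
    X_min = X[y == minority]
    nn = NearestNeighbors(n_neighbors=cfg.k_neighbors + 1).fit(X_min)
    _, neigh = nn.kneighbors(X_min)  # column 0 is the point itself
    rng = np.random.default_rng(cfg.seed)
    need = int(n_maj - n_min)
    base = rng.integers(0, n_min, size=need)
    pick = rng.integers(1, cfg.k_neighbors + 1, size=need)
    gap = rng.random(need)
    partner = neigh[base, pick]
    synth = X_min[base] + gap[:, None] * (X_min[partner] - X_min[base])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(need, minority, dtype=y.dtype)])
    return X_out, y_out


# ---------------------------------------------------------------------------
# Fitting and prediction
# ---------------------------------------------------------------------------

def fit_bayesian_logistic(
    X: np.ndarray,
    y: np.ndarray,
    prior_sd: float = 1.0,
    sampler: SamplerConfig = SamplerConfig(),
    vocabulary: tuple[str, ...] | None = None,
    scaler: Scaler | None = None,
) -> LogisticRiskModel:
    """Fit the Bayesian logistic record classifier.

    When ``scaler`` is None, X is standardized internally and the fitted
    scaler stored; when a scaler is supplied, X is assumed already on that
    standardized scale (the pipeline standardizes before oversampling).
    Point estimates are posterior means; the split R-hat diagnostic is
    recorded on the fit.
    """
    X = np.asarray(X, dtype=np.float64)
    if vocabulary is None:
        vocabulary = tuple(f"x{i}" for i in range(X.shape[1]))
    if len(vocabulary) != X.shape[1]:
        raise ModelError("vocabulary length must match feature count")
    if scaler is None:
        scaler = Scaler.fit(X)
        X = scaler.transform(X)
    fit = sample_logistic_posterior(X, y, prior_sd=prior_sd, cfg=sampler)
    mean = fit.mean
    return LogisticRiskModel(
        vocabulary=tuple(vocabulary),
        intercept=float(mean[0]),
        weights=mean[1:],
        posterior=fit,
        prior_sd=prior_sd,
        scaler=scaler,
        seed=sampler.seed,
    )


def predict_risk(
    model: LogisticRiskModel,
    dw_rows: np.ndarray,
    degenerate: np.ndarray | None = None,
) -> np.ndarray:
    """Risk probability sigmoid(b0 + d·beta) per feature row, on the raw DW
    scale (standardization applied internally).  Degenerate rows (no
    in-vocabulary tokens) are mapped to the neutral probability 0.5."""
    dw_rows = np.atleast_2d(np.asarray(dw_rows, dtype=np.float64))
    if dw_rows.shape[1] != len(model.vocabulary):
        raise ModelError(
            f"feature width {dw_rows.shape[1]} does not match model "
            f"vocabulary size {len(model.vocabulary)}"
        )
    z = model.intercept + model.scaler.transform(dw_rows) @ model.weights
    # keep probabilities in the open interval even for saturating logits
    p = np.clip(expit(z), 1e-12, 1.0 - 1e-12)
    if degenerate is not None:
        p = np.where(np.asarray(degenerate, dtype=bool), 0.5, p)
    return p


def significant_words(model: LogisticRiskModel, level: float = 0.95) -> list[str]:
    """Words whose equal-tailed (level) posterior credible interval for the
    coefficient excludes zero."""
    samples = model.posterior.samples[:, 1:]  # drop intercept
    n = samples.shape[0]
    if n < 2.0 / (1.0 - level):
        raise ModelError(
            f"{n} posterior draws cannot resolve the {level:.0%} credible interval"
        )
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(samples, alpha, axis=0)
    hi = np.quantile(samples, 1.0 - alpha, axis=0)
    mask = (lo > 0) | (hi < 0)
    return [w for w, m in zip(model.vocabulary, mask) if m]


def marginal_significance(
    X: np.ndarray, y: np.ndarray, prior_sd: float = 1.0, level: float = 0.95
) -> np.ndarray:
    """Per-feature marginal Bayesian significance mask.

    For every column j a univariate Bayesian logistic regression
    y ~ sigmoid(a_j + b_j x_j) with Normal(0, prior_sd²) priors is fitted by
    Newton iteration, and the Laplace (Gaussian) posterior of b_j is formed
    at the mode.  The feature is significant when the equal-tailed ``level``
    credible interval of b_j excludes zero.

    This marginal test is the operative per-word criterion of the selection
    ensemble: in the joint fit the DW feature space has rank at most the
    embedding dimension, so joint-coordinate posteriors are prior-dominated
    and their intervals never exclude zero.  All columns are fitted
    simultaneously (vectorised), so the screen costs a few matrix passes.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()[:, None]
    inv_var = 1.0 / prior_sd**2
    n, p = X.shape
    a = np.zeros(p)
    b = np.zeros(p)
    X2 = X * X
    for _ in range(25):
        z = a + X * b
        prob = expit(z)
        w = prob * (1.0 - prob)
        resid = y - prob
        g_a = resid.sum(axis=0) - inv_var * a
        g_b = (resid * X).sum(axis=0) - inv_var * b
        h_aa = w.sum(axis=0) + inv_var
        h_ab = (w * X).sum(axis=0)
        h_bb = (w * X2).sum(axis=0) + inv_var
        det = h_aa * h_bb - h_ab**2
        da = (h_bb * g_a - h_ab * g_b) / det
        db = (h_aa * g_b - h_ab * g_a) / det
        a += da
        b += db
        if max(np.abs(da).max(), np.abs(db).max()) < 1e-8:
            break
    # Laplace posterior sd of b at the mode
    z = a + X * b
    prob = expit(z)
    w = prob * (1.0 - prob)
    h_aa = w.sum(axis=0) + inv_var
    h_ab = (w * X).sum(axis=0)
    h_bb = (w * X2).sum(axis=0) + inv_var
    var_b = h_aa / (h_aa * h_bb - h_ab**2)
    from scipy.stats import norm

    crit = norm.ppf(0.5 + level / 2.0)
    return np.abs(b) > crit * np.sqrt(var_b)


# ---------------------------------------------------------------------------
# Ensemble vocabulary selection
# ---------------------------------------------------------------------------

def learning_features(
    learning: Corpus, cfg: PipelineConfig
) -> tuple[DocWordMatrix, "np.ndarray"]:
    """Vocabulary + embeddings on the learning corpus, returning the DW
    matrix and per-record 0/1 labels."""
    vocab = build_vocabulary(learning, top_k=cfg.embedding.top_k, min_count=cfg.embedding.min_count)
    W, D = train_embeddings(learning, vocab, cfg.embedding)
    dw = compute_dw(D, W)
    return dw, record_labels(learning, cfg.target)


def _sub_seed(seed: int, salt: int) -> int:
    return (seed * 100003 + salt * 7919 + 17) % (2**31)


def run_bisection_ensemble(
    learning: Corpus,
    cfg: PipelineConfig,
    seed: int = 0,
    dw: DocWordMatrix | None = None,
    y: np.ndarray | None = None,
    method: str = "marginal",
) -> SignificanceTally:
    """Three seeded patient-level bisections -> six primary models -> per-word
    significance counts.

    Embeddings (and hence DW) are shared across the six models: pass ``dw``
    and ``y`` to reuse precomputed learning-set features, otherwise they are
    built here.  Standardization uses full-learning-set statistics.

    ``method`` chooses the per-word significance criterion within each
    primary model: ``"marginal"`` (default) tests each word's univariate
    Bayesian posterior (see :func:`marginal_significance`); ``"joint"`` fits
    the full multivariate model by MCMC and tests each coordinate's credible
    interval — coherent only when the feature count does not exceed the
    embedding rank.
    """
    if method not in ("marginal", "joint"):
        raise ModelError(f"unknown significance method {method!r}")
    if dw is None or y is None:
        dw, y = learning_features(learning, cfg)
    rec_index = {doc_id: i for i, doc_id in enumerate(dw.doc_ids)}
    scaler = Scaler.fit(dw.DW)
    X_all = scaler.transform(dw.DW)
    counts = {w: 0 for w in dw.words}
    n_models = 0
    for b in range(cfg.bisections):
        spec = SplitSpec(seed=_sub_seed(seed, b), fraction=0.5, stratified=cfg.stratified_split)
        for half_idx, half in enumerate(split_patients(learning, spec)):
            pids = set(half.patients)
            rows = [
                rec_index[f"{r.patient_id}|{r.date.isoformat()}"]
                for r in learning.records
                if r.patient_id in pids
            ]
            X, y_half = X_all[rows], y[rows]
            if len(np.unique(y_half)) < 2:
                raise ModelError(
                    f"bisection {b} half {half_idx} lost a class; rerun with a different seed"
                )
            salt = 2 * b + half_idx
            Xb, yb = oversample_minority(
                X, y_half, OversampleConfig(k_neighbors=cfg.smote_k, seed=_sub_seed(seed, 100 + salt))
            )
            if method == "marginal":
                mask = marginal_significance(Xb, yb, prior_sd=cfg.prior_sd, level=cfg.level)
                sig = [w for w, m in zip(dw.words, mask) if m]
            else:
                model = fit_bayesian_logistic(
                    Xb,
                    yb,
                    prior_sd=cfg.prior_sd,
                    sampler=replace(cfg.sampler, seed=_sub_seed(seed, 200 + salt)),
                    vocabulary=dw.words,
                    scaler=scaler,
                )
                sig = significant_words(model, level=cfg.level)
            for w in sig:
                counts[w] += 1
            n_models += 1
    return SignificanceTally(words=dw.words, counts=counts, n_models=n_models, threshold=cfg.min_models)


def select_vocabulary(tally: SignificanceTally, min_models: int = 4) -> list[str]:
    """Words significant in at least ``min_models`` primary models, in
    vocabulary order."""
    if min_models > tally.n_models:
        warnings.warn(
            f"min_models={min_models} exceeds the {tally.n_models} primary models; "
            "no word can qualify",
            UserWarning,
            stacklevel=2,
        )
        return []
    return [w for w in tally.words if tally.counts.get(w, 0) >= min_models]


def build_final_model(
    learning: Corpus,
    selected: list[str],
    cfg: PipelineConfig,
    seed: int = 0,
    dw: DocWordMatrix | None = None,
    y: np.ndarray | None = None,
) -> LogisticRiskModel:
    """Refit on the full learning set restricted to the selected columns."""
    if not selected:
        raise ModelError("selected vocabulary is empty")
    if dw is None or y is None:
        dw, y = learning_features(learning, cfg)
    trimmed = trim_columns(dw, list(selected))
    scaler = Scaler.fit(trimmed.DW)
    X = scaler.transform(trimmed.DW)
    if len(np.unique(y)) < 2:
        raise ModelError("learning corpus must contain both classes")
    Xb, yb = oversample_minority(
        X, y, OversampleConfig(k_neighbors=cfg.smote_k, seed=_sub_seed(seed, 300))
    )
    return fit_bayesian_logistic(
        Xb,
        yb,
        prior_sd=cfg.prior_sd,
        sampler=replace(cfg.sampler, seed=_sub_seed(seed, 400)),
        vocabulary=tuple(selected),
        scaler=scaler,
    )
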