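"""Case-control evaluation of the fall-risk pipeline.

Record-level risk probabilities are averaged per patient into a patient risk
score; patients are then classified by thresholding the score at the ROC
point closest to (0, 1).  The reporting surface mirrors standard
case-control practice: confusion matrix, sensitivity, specificity (Wilson
intervals), odds ratio with a Woolf (log) interval, and cross-experiment
reproducibility as R² between patient scores of independent runs.

The precursor ("imminent") analysis reuses the identical machinery at the
record level: the classification target is whether a faller's record falls
in the 1–7 day window before a fall, and no patient aggregation is applied.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as _stats
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.proportion import proportion_confint

from .corpus import (
    Corpus,
    FALLER,
    IMMINENT,
    SplitSpec,
    UNTAGGED,
    filter_short_records,
    integrate_daily_records,
    split_patients,
    tokenize_corpus,
    stratify_by_stay,
    tag_imminent,
)
from .embedding import build_vocabulary, compute_dw, infer_doc_vectors, train_embeddings, trim_columns
from .riskmodel import (
    PipelineConfig,
    build_final_model,
    predict_risk,
    record_labels,
    run_bisection_ensemble,
    select_vocabulary,
)

POSITIVE_LABELS = frozenset({FALLER, IMMINENT})


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class PatientRiskScore:
    """Mean of one unit's record risk probabilities (for the record-level
    precursor analysis the unit is a single record, n_records = 1)."""

    patient_id: str
    score: float
    n_records: int
    label: str

    @property
    def positive(self) -> bool:
        return self.label in POSITIVE_LABELS


@dataclass
class RocCurve:
    points: list[tuple[float, float, float]]  # (fpr, tpr, cutoff)
    auc: float


@dataclass(frozen=True)
class ConfusionMatrix:
    """Rows: predicted risk / no-risk; columns: true positive / negative."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class IntervalStat:
    value: float
    lo: float
    hi: float


@dataclass
class StatsFragment:
    sensitivity: IntervalStat
    specificity: IntervalStat
    odds_ratio: IntervalStat
    continuity_corrected: bool = False


@dataclass
class EvaluationReport:
    auc: float
    threshold: float
    confusion: ConfusionMatrix
    stats: StatsFragment
    scores: list[PatientRiskScore]
    curve: RocCurve
    selected_vocabulary: list[str]
    seed: int
    unit: str = "patient"  # or "record"
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Scores and curves
# ---------------------------------------------------------------------------

def patient_scores(probabilities: dict[str, float], corpus: Corpus) -> list[PatientRiskScore]:
    """One score per patient: the arithmetic mean of that patient's record
    probabilities.  ``probabilities`` maps record id (patient_id|date) to the
    record's risk probability.  Patients with no scored record are excluded
    with a warning."""
    per_patient: dict[str, list[float]] = {}
    for rec in corpus.records:
        rid = f"{rec.patient_id}|{rec.date.isoformat()}"
        if rid in probabilities:
            per_patient.setdefault(rec.patient_id, []).append(float(probabilities[rid]))
    unknown = set(probabilities) - {
        f"{r.patient_id}|{r.date.isoformat()}" for r in corpus.records
    }
    if unknown:
        raise EvaluationError(f"scored records not in corpus: {sorted(unknown)[:3]}")
    missing = [pid for pid in corpus.patients if pid not in per_patient]
    if missing:
        warnings.warn(
            f"{len(missing)} patient(s) with zero scored records excluded",
            UserWarning,
            stacklevel=2,
        )
    return [
        PatientRiskScore(
            patient_id=pid,
            score=float(np.mean(vals)),
            n_records=len(vals),
            label=corpus.patients[pid].label,
        )
        for pid, vals in sorted(per_patient.items())
    ]


def _score_arrays(scores: list[PatientRiskScore]) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([1 if s.positive else 0 for s in scores])
    x = np.array([s.score for s in scores], dtype=float)
    return y, x


def roc(scores: list[PatientRiskScore]) -> RocCurve:
    """ROC curve over all distinct cutoffs (score >= cutoff => predicted
    positive) with trapezoidal AUC; tied scores step simultaneously."""
    y, x = _score_arrays(scores)
    if len(np.unique(y)) < 2:
        raise EvaluationError("ROC requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, x, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(points=list(zip(fpr.tolist(), tpr.tolist(), thr.tolist())), auc=auc)


def optimal_threshold(curve: RocCurve) -> float:
    """Cutoff whose ROC point is closest (Euclidean) to (0, 1); ties break
    to the lower cutoff."""
    if not curve.points:
        raise EvaluationError("empty ROC curve")
    best_d, best_cut = math.inf, math.inf
    for fpr, tpr, cut in curve.points:
        d = math.hypot(fpr, 1.0 - tpr)
        if d < best_d - 1e-12 or (abs(d - best_d) <= 1e-12 and cut < best_cut):
            best_d, best_cut = d, cut
    return float(best_cut)


def confusion_at(scores: list[PatientRiskScore], threshold: float) -> ConfusionMatrix:
    """Tabulate predicted risk (score >= threshold) against true labels."""
    y, x = _score_arrays(scores)
    pred = x >= threshold
    return ConfusionMatrix(
        tp=int(np.sum(pred & (y == 1))),
        fp=int(np.sum(pred & (y == 0))),
        fn=int(np.sum(~pred & (y == 1))),
        tn=int(np.sum(~pred & (y == 0))),
    )


def confusion_stats(
    cm: ConfusionMatrix, ci_method: str = "wilson", level: float = 0.95
) -> StatsFragment:
    """Sensitivity, specificity (Wilson or Wald CI) and the odds ratio with
    its Woolf log-interval; zero cells get the Haldane–Anscombe +0.5
    correction (flagged)."""
    if ci_method not in ("wilson", "wald"):
        raise EvaluationError(f"unknown ci_method {ci_method!r}")
    if cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0:
        raise EvaluationError("a margin of the confusion matrix is empty")
    alpha = 1.0 - level
    method = "wilson" if ci_method == "wilson" else "normal"

    def _prop(k: int, n: int) -> IntervalStat:
        lo, hi = proportion_confint(k, n, alpha=alpha, method=method)
        return IntervalStat(value=k / n, lo=float(lo), hi=float(hi))

    sens = _prop(cm.tp, cm.tp + cm.fn)
    spec = _prop(cm.tn, cm.tn + cm.fp)

    cells = [cm.tp, cm.fp, cm.fn, cm.tn]
    corrected = any(c == 0 for c in cells)
    a, b, c, d = [c + 0.5 for c in cells] if corrected else cells
    or_value = (a * d) / (b * c)
    z = _stats.norm.ppf(1.0 - alpha / 2.0)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    or_ci = IntervalStat(
        value=or_value,
        lo=math.exp(math.log(or_value) - z * se),
        hi=math.exp(math.log(or_value) + z * se),
    )
    return StatsFragment(
        sensitivity=sens, specificity=spec, odds_ratio=or_ci, continuity_corrected=corrected
    )


def cross_run_r2(scores_a: list[PatientRiskScore], scores_b: list[PatientRiskScore]) -> float:
    """Coefficient of determination of the OLS regression of run B's patient
    scores on run A's (identical patient sets required)."""
    map_a = {s.patient_id: s.score for s in scores_a}
    map_b = {s.patient_id: s.score for s in scores_b}
    if set(map_a) != set(map_b):
        raise EvaluationError("patient sets differ between runs")
    ids = sorted(map_a)
    a = np.array([map_a[i] for i in ids])
    b = np.array([map_b[i] for i in ids])
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise EvaluationError(
            "scores are constant in one run (neutral model?); R^2 undefined"
        )
    result = _stats.linregress(a, b)
    return float(result.rvalue**2)


# ---------------------------------------------------------------------------
# End-to-end experiments
# ---------------------------------------------------------------------------

def _exp_seed(seed: int, salt: int) -> int:
    return (seed * 9176 + salt * 31 + 5) % (2**31)


def _report_from_scores(
    scores: list[PatientRiskScore], selected: list[str], seed: int, unit: str, extras: dict
) -> EvaluationReport:
    curve = roc(scores)
    threshold = optimal_threshold(curve)
    cm = confusion_at(scores, threshold)
    return EvaluationReport(
        auc=curve.auc,
        threshold=threshold,
        confusion=cm,
        stats=confusion_stats(cm),
        scores=scores,
        curve=curve,
        selected_vocabulary=selected,
        seed=seed,
        unit=unit,
        extras=extras,
    )


def _model_and_score(
    learning: Corpus, test: Corpus, cfg: PipelineConfig, seed: int
) -> tuple[np.ndarray, np.ndarray, list[str], dict]:
    """Shared modelling core: embeddings on learning, ensemble selection,
    final model, probabilities for the test records.  Returns (probs,
    degenerate mask, selected words, extras)."""
    vocab = build_vocabulary(learning, top_k=cfg.embedding.top_k, min_count=cfg.embedding.min_count)
    emb = replace(cfg.embedding, seed=_exp_seed(seed, 2))
    W, D = train_embeddings(learning, vocab, emb)
    dw_learn = compute_dw(D, W)
    y_learn = record_labels(learning, cfg.target)
    tally = run_bisection_ensemble(learning, cfg, seed=_exp_seed(seed, 3), dw=dw_learn, y=y_learn)
    selected = select_vocabulary(tally, min_models=cfg.min_models)
    if not selected:
        # no vocabulary qualifies (expected under a null corpus): fall back
        # to the uninformative model that scores every record 0.5
        warnings.warn(
            "no word was significant in enough primary models; "
            "using the neutral model (all probabilities 0.5)",
            UserWarning,
            stacklevel=2,
        )
        D_test = infer_doc_vectors(test, vocab, W, replace(emb, seed=_exp_seed(seed, 5)))
        probs = np.full(len(D_test.doc_ids), 0.5)
        extras = {
            "n_selected": 0,
            "tally": tally,
            "model_converged": True,
            "test_doc_ids": D_test.doc_ids,
        }
        return probs, D_test.degenerate, [], extras
    model = build_final_model(
        learning, selected, cfg, seed=_exp_seed(seed, 4), dw=dw_learn, y=y_learn
    )
    D_test = infer_doc_vectors(test, vocab, W, replace(emb, seed=_exp_seed(seed, 5)))
    dw_test = trim_columns(compute_dw(D_test, W), selected)
    probs = predict_risk(model, dw_test.DW, degenerate=dw_test.degenerate)
    extras = {
        "n_selected": len(selected),
        "tally": tally,
        "model_converged": model.converged,
        "final_weights": dict(zip(model.vocabulary, model.weights.tolist())),
        "test_doc_ids": dw_test.doc_ids,
    }
    return probs, dw_test.degenerate, selected, extras


def prepare_corpus(corpus: Corpus, cfg: PipelineConfig) -> Corpus:
    """Tokenization (for raw-text records), same-day integration, and the
    short-record exclusion filter."""
    return filter_short_records(
        integrate_daily_records(tokenize_corpus(corpus)), min_chars=cfg.min_chars
    )


def run_experiment(corpus: Corpus, cfg: PipelineConfig, seed: int = 0) -> EvaluationReport:
    """One full replicate of the fall-prediction experiment: prepare, split
    patients into learning/test halves, embed, select vocabulary with the
    six-model ensemble, fit the final model, and evaluate patient risk
    scores on the held-out test patients."""
    prepared = prepare_corpus(corpus, cfg)
    learning, test = split_patients(
        prepared,
        SplitSpec(seed=_exp_seed(seed, 1), fraction=cfg.split_fraction, stratified=cfg.stratified_split),
    )
    probs, _, selected, extras = _model_and_score(learning, test, cfg, seed)
    prob_map = dict(zip(extras.pop("test_doc_ids"), probs.tolist()))
    scores = patient_scores(prob_map, test)
    return _report_from_scores(scores, selected, seed, unit="patient", extras=extras)


def run_imminent_experiment(
    fallers: Corpus,
    cfg: PipelineConfig,
    seed: int = 0,
    window_days: int = 7,
    stratum: str = "all",
) -> EvaluationReport:
    """Precursor analysis on a faller-only corpus: tag records imminent
    (1..window days before a fall), optionally restrict to a stay-length
    stratum, then run the same pipeline at the RECORD level (classification
    target = imminent tag; no patient aggregation)."""
    non_fallers = [p for p in fallers.patients.values() if p.label != FALLER]
    if non_fallers:
        raise EvaluationError("the precursor analysis expects a faller-only corpus")
    prepared = prepare_corpus(fallers, cfg)
    if any(r.imminent == UNTAGGED for r in prepared.records):
        prepared = tag_imminent(prepared, window_days=window_days)
    if stratum != "all":
        long_c, short_c, _ = stratify_by_stay(prepared)
        prepared = {"long": long_c, "short": short_c}[stratum]
    if not any(r.imminent == IMMINENT for r in prepared.records):
        raise EvaluationError("no imminent records in the corpus/stratum")
    cfg = replace(cfg, target="imminent")
    learning, test = split_patients(
        prepared,
        SplitSpec(seed=_exp_seed(seed, 1), fraction=cfg.split_fraction, stratified=False),
    )
    probs, degenerate, selected, extras = _model_and_score(learning, test, cfg, seed)
    doc_ids = extras.pop("test_doc_ids")
    tag_by_id = {
        f"{r.patient_id}|{r.date.isoformat()}": r.imminent for r in test.records
    }
    scores = [
        PatientRiskScore(patient_id=rid, score=float(p), n_records=1, label=tag_by_id[rid])
        for rid, p in zip(doc_ids, probs)
    ]
    extras["stratum"] = stratum
    extras["window_days"] = window_days
    return _report_from_scores(scores, selected, seed, unit="record", extras=extras)


def report_dict(rep: EvaluationReport) -> dict:
    """JSON-serialisable summary of an evaluation report (display rounding:
    3 decimals for proportions, 2 for odds ratios)."""
    st = rep.stats
    return {
        "auc": round(rep.auc, 3),
        "threshold": round(rep.threshold, 4),
        "unit": rep.unit,
        "confusion": {"tp": rep.confusion.tp, "fp": rep.confusion.fp,
                      "fn": rep.confusion.fn, "tn": rep.confusion.tn},
        "sensitivity": round(st.sensitivity.value, 3),
        "sensitivity_ci": [round(st.sensitivity.lo, 3), round(st.sensitivity.hi, 3)],
        "specificity": round(st.specificity.value, 3),
        "specificity_ci": [round(st.specificity.lo, 3), round(st.specificity.hi, 3)],
        "odds_ratio": round(st.odds_ratio.value, 2),
        "odds_ratio_ci": [round(st.odds_ratio.lo, 2), round(st.odds_ratio.hi, 2)],
        "n_selected": len(rep.selected_vocabulary),
        "n_scored": len(rep.scores),
        "seed": rep.seed,
    }


@dataclass
class RepeatedRuns:
    reports: list[EvaluationReport]
    summary: dict[str, tuple[float, float]]  # statistic -> (mean, sample SD)
    pairwise_r2: dict[tuple[int, int], float]


def run_repeated(
    corpus: Corpus,
    cfg: PipelineConfig,
    seeds: list[int],
    imminent: bool = False,
    **imminent_kwargs,
) -> RepeatedRuns:
    """Independent replicates with different seeds, summarised as mean
    (sample SD) of AUC / sensitivity / specificity / odds ratio plus all
    pairwise score R² values.  Scores of two runs are compared on the
    intersection of their scored units (test splits differ across seeds)."""
    runner = run_imminent_experiment if imminent else run_experiment
    reports = [runner(corpus, cfg, seed=s, **imminent_kwargs) for s in seeds]

    def _mean_sd(vals: list[float]) -> tuple[float, float]:
        arr = np.asarray(vals, dtype=float)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        return float(arr.mean()), sd

    summary = {
        "auc": _mean_sd([r.auc for r in reports]),
        "sensitivity": _mean_sd([r.stats.sensitivity.value for r in reports]),
        "specificity": _mean_sd([r.stats.specificity.value for r in reports]),
        "odds_ratio": _mean_sd([r.stats.odds_ratio.value for r in reports]),
    }
    pairwise: dict[tuple[int, int], float] = {}
    for i, j in itertools.combinations(range(len(reports)), 2):
        ids = {s.patient_id for s in reports[i].scores} & {s.patient_id for s in reports[j].scores}
        if len(ids) < 3:
            continue
        a = [s for s in reports[i].scores if s.patient_id in ids]
        b = [s for s in reports[j].scores if s.patient_id in ids]
        try:
            pairwise[(i, j)] = cross_run_r2(a, b)
        except EvaluationError:
            continue  # a neutral (constant-score) run has no defined R^2
    return RepeatedRuns(reports=reports, summary=summary, pairwise_r2=pairwise)
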