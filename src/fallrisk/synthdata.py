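"""Seeded synthetic case-control corpora with known ground truth.

The generator emulates the structure of a nursing-record corpus without
imitating clinical language: two patient classes (faller / nonfaller) in
which fallers accumulate more per-day records than nonfallers, token streams
drawn from a Zipf-like background vocabulary shared by both classes, a small
set of planted "risk" tokens enriched in faller records (and "protective"
tokens enriched in nonfaller records) by a configurable log frequency-ratio,
and planted "precursor" tokens whose frequency is boosted inside the 1–7 day
window before each fall.  Every statistical property the pipeline consumes —
vocabulary ranks, record-count imbalance, the short-record filter, imminent
windows, stay-length heterogeneity — is exercised with known truth.

Tokens are emitted pre-tokenized as ASCII pseudo-words (``w0013``), so no
morphological analysis is involved.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, replace

import numpy as np

from .corpus import Corpus, FALLER, NONFALLER, NursingRecord, PatientRecord

_START = _dt.date(2014, 7, 1)


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """Defaults are the standard benchmark conditions: 150 fallers / 200
    nonfallers, 2000 background words, 20 risk + 10 protective tokens at a
    log frequency-ratio of 1.0, negative-binomial record counts with mean 50
    (fallers) / 30 (nonfallers), ~80 tokens per record, 15 precursor tokens
    boosted 3× inside the 7-day pre-fall window."""

    n_fallers: int = 150
    n_nonfallers: int = 200
    vocab_size: int = 2000
    n_risk_tokens: int = 20
    n_protective_tokens: int = 10
    n_precursor_tokens: int = 15
    effect_log_odds: float = 1.0
    records_mean_faller: float = 50.0
    records_mean_nonfaller: float = 30.0
    records_dispersion: float = 4.0
    tokens_per_record: float = 80.0
    tokens_dispersion: float = 20.0
    imminent_window: int = 7
    precursor_boost: float = 3.0
    short_record_rate: float = 0.05
    planted_base_prob: float = 0.003
    zipf_exponent: float = 1.0
    extra_falls_mean: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fallers < 1 or self.n_nonfallers < 1:
            raise GeneratorError("need at least one patient per class")
        if self.vocab_size < 1 or self.tokens_per_record < 1:
            raise GeneratorError("degenerate vocabulary or record length")
        if self.precursor_boost <= 0:
            raise GeneratorError("precursor_boost must be positive")


@dataclass
class GroundTruth:
    risk_tokens: tuple[str, ...]
    protective_tokens: tuple[str, ...]
    precursor_tokens: tuple[str, ...]
    tokens: tuple[str, ...]
    faller_probs: np.ndarray
    nonfaller_probs: np.ndarray
    imminent_probs: np.ndarray
    fall_dates: dict[str, tuple[_dt.date, ...]]
    labels: dict[str, str]


def _distributions(cfg: GeneratorConfig):
    background = [f"w{i:04d}" for i in range(cfg.vocab_size)]
    risk = tuple(f"risk{i:03d}" for i in range(cfg.n_risk_tokens))
    prot = tuple(f"prot{i:03d}" for i in range(cfg.n_protective_tokens))
    prec = tuple(f"prec{i:03d}" for i in range(cfg.n_precursor_tokens))
    tokens = tuple(background) + risk + prot + prec

    zipf = 1.0 / np.arange(1, cfg.vocab_size + 1) ** cfg.zipf_exponent
    zipf /= zipf.sum()
    base = np.concatenate(
        [zipf, np.full(len(risk) + len(prot) + len(prec), cfg.planted_base_prob)]
    )
    nb = cfg.vocab_size
    nr, npr = cfg.n_risk_tokens, cfg.n_protective_tokens

    nonfaller = base.copy()
    faller = base.copy()
    faller[nb : nb + nr] *= np.exp(cfg.effect_log_odds)
    faller[nb + nr : nb + nr + npr] *= np.exp(-cfg.effect_log_odds)
    imminent = faller.copy()
    imminent[nb + nr + npr :] *= cfg.precursor_boost

    return tokens, risk, prot, prec, (
        nonfaller / nonfaller.sum(),
        faller / faller.sum(),
        imminent / imminent.sum(),
    )


def _record_count(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    p = dispersion / (dispersion + mean)
    return max(2, int(rng.negative_binomial(dispersion, p)))


def generate_corpus(cfg: GeneratorConfig) -> tuple[Corpus, GroundTruth]:
    """Deterministic synthetic corpus + ground truth for ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    tokens, risk, prot, prec, (p_non, p_fall, p_imm) = _distributions(cfg)
    token_arr = np.array(tokens)

    patients: dict[str, PatientRecord] = {}
    records: list[NursingRecord] = []
    truth_falls: dict[str, tuple[_dt.date, ...]] = {}
    labels: dict[str, str] = {}

    plan = [(FALLER, f"F{i:04d}") for i in range(cfg.n_fallers)] + [
        (NONFALLER, f"N{i:04d}") for i in range(cfg.n_nonfallers)
    ]
    for label, pid in plan:
        mean = cfg.records_mean_faller if label == FALLER else cfg.records_mean_nonfaller
        n_rec = _record_count(rng, mean, cfg.records_dispersion)
        start = _START + _dt.timedelta(days=int(rng.integers(0, 365)))
        dates = [start + _dt.timedelta(days=i) for i in range(n_rec)]

        fall_dates: tuple[_dt.date, ...] = ()
        imminent_days = np.zeros(n_rec, dtype=bool)
        if label == FALLER:
            n_falls = min(n_rec, 1 + int(rng.poisson(cfg.extra_falls_mean)))
            idx = np.sort(rng.choice(n_rec, size=n_falls, replace=False))
            fall_dates = tuple(dates[i] for i in idx)
            for i in idx:
                lo = max(0, i - cfg.imminent_window)
                imminent_days[lo:i] = True

        age_mu, age_sd = (73.0, 13.0) if label == FALLER else (65.0, 18.0)
        patients[pid] = PatientRecord(
            patient_id=pid,
            label=label,
            fall_dates=fall_dates,
            age=round(float(np.clip(rng.normal(age_mu, age_sd), 18, 100)), 1),
            sex="F" if rng.random() < 0.5 else "M",
        )
        truth_falls[pid] = fall_dates
        labels[pid] = label

        for i, date in enumerate(dates):
            if rng.random() < cfg.short_record_rate:
                n_tok = int(rng.integers(1, 11))  # <= 50 chars: filtered out
            else:
                p = cfg.tokens_dispersion / (cfg.tokens_dispersion + cfg.tokens_per_record)
                n_tok = max(20, int(rng.negative_binomial(cfg.tokens_dispersion, p)))
            if label == FALLER:
                dist = p_imm if imminent_days[i] else p_fall
            else:
                dist = p_non
            draw = rng.choice(len(tokens), size=n_tok, p=dist)
            toks = tuple(str(t) for t in token_arr[draw])
            records.append(
                NursingRecord(
                    patient_id=pid,
                    date=date,
                    tokens=toks,
                    char_count=sum(len(t) for t in toks),
                )
            )

    corpus = Corpus(patients=patients, records=records)
    corpus.log(
        f"synthetic corpus: seed={cfg.seed}, {cfg.n_fallers} fallers, "
        f"{cfg.n_nonfallers} nonfallers, effect={cfg.effect_log_odds}, "
        f"boost={cfg.precursor_boost}"
    )
    truth = GroundTruth(
        risk_tokens=risk,
        protective_tokens=prot,
        precursor_tokens=prec,
        tokens=tokens,
        faller_probs=p_fall,
        nonfaller_probs=p_non,
        imminent_probs=p_imm,
        fall_dates=truth_falls,
        labels=labels,
    )
    return corpus, truth


def null_corpus(cfg: GeneratorConfig) -> tuple[Corpus, GroundTruth]:
    """Corpus in which the class labels carry no signal: token effects and
    the precursor boost are zeroed and both classes share the nonfaller
    record-count distribution.  Ground-truth planted lists are empty."""
    null_cfg = replace(
        cfg,
        effect_log_odds=0.0,
        precursor_boost=1.0,
        records_mean_faller=cfg.records_mean_nonfaller,
    )
    corpus, truth = generate_corpus(null_cfg)
    truth = replace_truth_planted(truth)
    corpus.log("null corpus: all class effects zeroed")
    return corpus, truth


def replace_truth_planted(truth: GroundTruth) -> GroundTruth:
    return GroundTruth(
        risk_tokens=(),
        protective_tokens=(),
        precursor_tokens=(),
        tokens=truth.tokens,
        faller_probs=truth.faller_probs,
        nonfaller_probs=truth.nonfaller_probs,
        imminent_probs=truth.imminent_probs,
        fall_dates=truth.fall_dates,
        labels=truth.labels,
    )


def standard_benchmark() -> GeneratorConfig:
    """The frozen benchmark configuration (see :class:`GeneratorConfig`
    defaults); set ``seed`` via :func:`dataclasses.replace`."""
    return GeneratorConfig()
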