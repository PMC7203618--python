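"""Case-control corpus of per-patient nursing records.

The corpus is the shared substrate of the pipeline: patients carry the
case-control label (``faller`` / ``nonfaller``) and their fall dates, while
nursing records carry one day's integrated free text (or pre-tokenized token
stream) per patient.  All downstream stages — embedding, risk modelling,
evaluation — consume the validated :class:`Corpus` produced here.

Records may arrive either as raw text (tokenized later through a pluggable
tokenizer callable) or pre-tokenized; synthetic corpora are pre-tokenized, so
no morphological analyzer is required.
"""

from __future__ import annotations

import datetime as _dt
import os
import random
from dataclasses import dataclass, field, replace

import pandas as pd

FALLER = "faller"
NONFALLER = "nonfaller"

IMMINENT = "imminent"
NOT_IMMINENT = "not_imminent"
UNTAGGED = "untagged"

RECORDS_FILE = "records.tsv"
PATIENTS_FILE = "patients.tsv"
PROVENANCE_FILE = "provenance.txt"


class CorpusError(ValueError):
    """Raised for malformed or referentially inconsistent corpus inputs."""


def whitespace_tokenizer(text: str) -> list[str]:
    """Default tokenizer: split on whitespace.  Swap in a morphological
    analyzer adapter for raw Japanese clinical text."""
    return text.split()


def content_char_count(text: str) -> int:
    """Script-agnostic proxy for the character count used by the exclusion
    filter: number of non-whitespace characters."""
    return sum(1 for c in text if not c.isspace())


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    label: str
    fall_dates: tuple[_dt.date, ...] = ()
    age: float | None = None
    sex: str = "unknown"
    division: str | None = None

    def __post_init__(self) -> None:
        if self.label not in (FALLER, NONFALLER):
            raise CorpusError(f"unknown label {self.label!r} for patient {self.patient_id}")
        if (self.label == FALLER) != bool(self.fall_dates):
            raise CorpusError(
                f"patient {self.patient_id}: label {self.label!r} inconsistent with "
                f"{len(self.fall_dates)} fall date(s)"
            )
        if any(b <= a for a, b in zip(self.fall_dates, self.fall_dates[1:])):
            raise CorpusError(f"patient {self.patient_id}: fall dates must be strictly increasing")


@dataclass(frozen=True)
class NursingRecord:
    """One per-patient-per-day note (after integration).

    ``char_count`` is the content-character count of the original text and is
    consumed only by the exclusion filter; for pre-tokenized records it is the
    sum of token lengths.
    """

    patient_id: str
    date: _dt.date
    tokens: tuple[str, ...] = ()
    text: str = ""
    char_count: int = 0
    imminent: str = UNTAGGED

    def __post_init__(self) -> None:
        if self.char_count < 0:
            raise CorpusError("char_count must be >= 0")
        if self.imminent not in (IMMINENT, NOT_IMMINENT, UNTAGGED):
            raise CorpusError(f"bad imminent tag {self.imminent!r}")


@dataclass
class Corpus:
    patients: dict[str, PatientRecord]
    records: list[NursingRecord]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.patient_id not in self.patients:
                raise CorpusError(f"record dated {rec.date} cites unknown patient {rec.patient_id!r}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return (
            self.patients == other.patients
            and sorted(self.records, key=lambda r: (r.patient_id, r.date))
            == sorted(other.records, key=lambda r: (r.patient_id, r.date))
            and self.provenance == other.provenance
        )

    def log(self, message: str) -> None:
        self.provenance.append(message)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_records(self) -> int:
        return len(self.records)

    def records_of(self, patient_id: str) -> list[NursingRecord]:
        return [r for r in self.records if r.patient_id == patient_id]

    def record_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {pid: 0 for pid in self.patients}
        for rec in self.records:
            counts[rec.patient_id] += 1
        return counts

    def labels(self) -> dict[str, str]:
        return {pid: p.label for pid, p in self.patients.items()}

    def subset(self, patient_ids, note: str | None = None) -> "Corpus":
        """Corpus restricted to the given patients (all their records)."""
        keep = set(patient_ids)
        unknown = keep - set(self.patients)
        if unknown:
            raise CorpusError(f"unknown patient ids in subset: {sorted(unknown)[:5]}")
        sub = Corpus(
            patients={pid: self.patients[pid] for pid in self.patients if pid in keep},
            records=[r for r in self.records if r.patient_id in keep],
            provenance=list(self.provenance),
        )
        if note:
            sub.log(note)
        return sub


@dataclass(frozen=True)
class SplitSpec:
    """Patient-level random bisection: first part receives
    ``floor(fraction * n)`` patients (per class when stratified)."""

    seed: int
    fraction: float = 0.5
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction < 1.0:
            raise CorpusError(f"fraction must lie in (0, 1), got {self.fraction}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_date(value: str, where: str) -> _dt.date:
    try:
        return _dt.date.fromisoformat(value)
    except ValueError as exc:
        raise CorpusError(f"{where}: bad ISO-8601 date {value!r}") from exc


def read_corpus(records_path: str, patients_path: str | None = None) -> Corpus:
    """Read a corpus from its two delimited text files.

    ``records_path`` may instead be a directory containing ``records.tsv``,
    ``patients.tsv`` and optionally ``provenance.txt``.
    Records are tab-separated ``patient_id, date, tokens|text[, imminent]``;
    a ``tokens`` field is space-joined.  Patients are tab-separated
    ``patient_id, label, fall_dates[, age, sex, division]`` with fall dates
    semicolon-joined ISO dates.
    """
    provenance: list[str] = []
    if patients_path is None:
        root = records_path
        records_path = os.path.join(root, RECORDS_FILE)
        patients_path = os.path.join(root, PATIENTS_FILE)
        prov_path = os.path.join(root, PROVENANCE_FILE)
        if os.path.exists(prov_path):
            with open(prov_path, encoding="utf-8") as fh:
                provenance = [line.rstrip("\n") for line in fh if line.strip()]

    patients: dict[str, PatientRecord] = {}
    pt = pd.read_csv(patients_path, sep="\t", dtype=str, keep_default_na=False)
    required = {"patient_id", "label"}
    if not required <= set(pt.columns):
        raise CorpusError(f"patients file lacks columns {sorted(required - set(pt.columns))}")
    for i, row in enumerate(pt.itertuples(index=False), start=2):
        pid = row.patient_id
        if pid in patients:
            raise CorpusError(f"patients file line {i}: duplicate patient_id {pid!r}")
        falls = tuple(
            _parse_date(d, f"patients file line {i}")
            for d in getattr(row, "fall_dates", "").split(";")
            if d
        )
        age_raw = getattr(row, "age", "")
        patients[pid] = PatientRecord(
            patient_id=pid,
            label=row.label,
            fall_dates=falls,
            age=float(age_raw) if age_raw else None,
            sex=getattr(row, "sex", "") or "unknown",
            division=getattr(row, "division", "") or None,
        )

    records: list[NursingRecord] = []
    with open(records_path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: j for j, name in enumerate(header)}
        if "patient_id" not in idx or "date" not in idx or not ({"tokens", "text"} & set(idx)):
            raise CorpusError("records file must have patient_id, date and tokens|text columns")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise CorpusError(
                    f"records file line {lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            pid = parts[idx["patient_id"]]
            if pid not in patients:
                raise CorpusError(f"records file line {lineno}: unknown patient_id {pid!r}")
            date = _parse_date(parts[idx["date"]], f"records file line {lineno}")
            tokens: tuple[str, ...] = ()
            text = ""
            if "tokens" in idx and parts[idx["tokens"]]:
                tokens = tuple(parts[idx["tokens"]].split(" "))
                char_count = sum(len(t) for t in tokens)
            else:
                text = parts[idx.get("text", idx.get("tokens"))]
                char_count = content_char_count(text)
            tag = parts[idx["imminent"]] if "imminent" in idx else UNTAGGED
            records.append(
                NursingRecord(
                    patient_id=pid,
                    date=date,
                    tokens=tokens,
                    text=text,
                    char_count=char_count,
                    imminent=tag or UNTAGGED,
                )
            )
    return Corpus(patients=patients, records=records, provenance=provenance)


def write_corpus(corpus: Corpus, path: str) -> None:
    """Serialize to a directory in the format :func:`read_corpus` accepts."""
    os.makedirs(path, exist_ok=True)
    with open(os.path.join(path, RECORDS_FILE), "w", encoding="utf-8") as fh:
        fh.write("patient_id\tdate\ttokens\ttext\timminent\n")
        for rec in sorted(corpus.records, key=lambda r: (r.patient_id, r.date)):
            fh.write(
                f"{rec.patient_id}\t{rec.date.isoformat()}\t{' '.join(rec.tokens)}\t"
                f"{rec.text}\t{rec.imminent}\n"
            )
    with open(os.path.join(path, PATIENTS_FILE), "w", encoding="utf-8") as fh:
        fh.write("patient_id\tlabel\tfall_dates\tage\tsex\tdivision\n")
        for pid in sorted(corpus.patients):
            p = corpus.patients[pid]
            falls = ";".join(d.isoformat() for d in p.fall_dates)
            age = "" if p.age is None else repr(p.age)
            fh.write(f"{pid}\t{p.label}\t{falls}\t{age}\t{p.sex}\t{p.division or ''}\n")
    with open(os.path.join(path, PROVENANCE_FILE), "w", encoding="utf-8") as fh:
        for line in corpus.provenance:
            fh.write(line + "\n")


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def tokenize_corpus(corpus: Corpus, tokenizer=whitespace_tokenizer) -> Corpus:
    """Tokenize raw-text records in place of their text using ``tokenizer``.

    Pre-tokenized records pass through unchanged.  ``char_count`` keeps the
    original text's content-character count.
    """
    records = [
        rec if rec.tokens else replace(rec, tokens=tuple(tokenizer(rec.text)))
        for rec in corpus.records
    ]
    out = Corpus(patients=dict(corpus.patients), records=records, provenance=list(corpus.provenance))
    out.log("tokenize")
    return out


def integrate_daily_records(corpus: Corpus) -> Corpus:
    """Merge all of a patient's same-day records into one nursing record.

    Tokens and texts concatenate in input order; char_counts add.  Idempotent.
    """
    grouped: dict[tuple[str, _dt.date], list[NursingRecord]] = {}
    order: list[tuple[str, _dt.date]] = []
    for rec in corpus.records:
        key = (rec.patient_id, rec.date)
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(rec)
    merged = []
    for key in order:
        group = grouped[key]
        if len(group) == 1:
            merged.append(group[0])
            continue
        merged.append(
            NursingRecord(
                patient_id=key[0],
                date=key[1],
                tokens=tuple(t for rec in group for t in rec.tokens),
                text=" ".join(rec.text for rec in group if rec.text),
                char_count=sum(rec.char_count for rec in group),
                imminent=group[0].imminent,
            )
        )
    out = Corpus(patients=dict(corpus.patients), records=merged, provenance=list(corpus.provenance))
    out.log(f"integrate_daily_records: {corpus.n_records} -> {out.n_records}")
    return out


def filter_short_records(corpus: Corpus, min_chars: int = 50) -> Corpus:
    """Drop records whose content-character count is not strictly greater
    than ``min_chars`` (default: more than 50 characters required)."""
    if min_chars < 0:
        raise CorpusError(f"min_chars must be >= 0, got {min_chars}")
    kept = [rec for rec in corpus.records if rec.char_count > min_chars]
    removed: dict[str, int] = {FALLER: 0, NONFALLER: 0}
    for rec in corpus.records:
        if rec.char_count <= min_chars:
            removed[corpus.patients[rec.patient_id].label] += 1
    out = Corpus(patients=dict(corpus.patients), records=kept, provenance=list(corpus.provenance))
    out.log(
        f"filter_short_records(min_chars={min_chars}): removed "
        f"{removed[FALLER]} faller and {removed[NONFALLER]} nonfaller records"
    )
    return out


def tag_imminent(corpus: Corpus, window_days: int = 7, include_fall_day: bool = False) -> Corpus:
    """Tag each faller record as ``imminent`` when it falls in the 1..window
    days before any of the patient's falls (the fall day itself only when
    ``include_fall_day``); other faller records become ``not_imminent`` and
    nonfaller records stay ``untagged``."""
    if window_days < 1:
        raise CorpusError(f"window_days must be >= 1, got {window_days}")
    records = []
    for rec in corpus.records:
        patient = corpus.patients[rec.patient_id]
        if patient.label != FALLER:
            records.append(replace(rec, imminent=UNTAGGED))
            continue
        hit = False
        for fall in patient.fall_dates:
            delta = (fall - rec.date).days
            lo = 0 if include_fall_day else 1
            if lo <= delta <= window_days:
                hit = True
                break
        records.append(replace(rec, imminent=IMMINENT if hit else NOT_IMMINENT))
    out = Corpus(patients=dict(corpus.patients), records=records, provenance=list(corpus.provenance))
    n_imm = sum(r.imminent == IMMINENT for r in records)
    out.log(f"tag_imminent(window={window_days}, include_fall_day={include_fall_day}): {n_imm} imminent")
    return out


def stratify_by_stay(
    corpus: Corpus, long_min: int = 61, short_max: int = 45
) -> tuple[Corpus, Corpus, Corpus]:
    """Partition *faller* patients by per-patient record count into
    (long-stay, short-stay, unassigned) corpora: long when count >= long_min
    (more than 60 records), short when count <= short_max."""
    if long_min <= short_max:
        raise CorpusError("long_min must exceed short_max")
    counts = corpus.record_counts()
    fallers = [pid for pid, p in corpus.patients.items() if p.label == FALLER]
    long_ids = [pid for pid in fallers if counts[pid] >= long_min]
    short_ids = [pid for pid in fallers if counts[pid] <= short_max]
    mid_ids = [pid for pid in fallers if short_max < counts[pid] < long_min]
    return (
        corpus.subset(long_ids, note=f"stratify_by_stay: long (>= {long_min} records)"),
        corpus.subset(short_ids, note=f"stratify_by_stay: short (<= {short_max} records)"),
        corpus.subset(mid_ids, note="stratify_by_stay: unassigned"),
    )


def split_patients(corpus: Corpus, spec: SplitSpec) -> tuple[Corpus, Corpus]:
    """Random patient-level bisection into (first, second) sub-corpora.

    Deterministic given ``spec.seed``; the first part receives
    ``floor(fraction * n)`` patients, per class when stratified.
    """
    if corpus.n_patients < 2:
        raise CorpusError("need at least 2 patients to split")
    rng = random.Random(spec.seed)
    first: list[str] = []
    if spec.stratified:
        groups = [
            sorted(pid for pid, p in corpus.patients.items() if p.label == lab)
            for lab in (FALLER, NONFALLER)
        ]
    else:
        groups = [sorted(corpus.patients)]
    for ids in groups:
        if not ids:
            continue
        shuffled = ids[:]
        rng.shuffle(shuffled)
        first.extend(shuffled[: int(spec.fraction * len(shuffled))])
    second = [pid for pid in corpus.patients if pid not in set(first)]
    note_a = f"split_patients(seed={spec.seed}, fraction={spec.fraction}): part 1/2"
    note_b = f"split_patients(seed={spec.seed}, fraction={spec.fraction}): part 2/2"
    return corpus.subset(first, note=note_a), corpus.subset(second, note=note_b)
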