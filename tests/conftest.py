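import datetime as dt

import pytest

from fallrisk.corpus import Corpus, NursingRecord, PatientRecord


def day(n: int) -> dt.date:
    return dt.date(2014, 7, 1) + dt.timedelta(days=n)


def patient(pid: str, label: str = "nonfaller", falls: tuple[int, ...] = ()) -> PatientRecord:
    return PatientRecord(
        patient_id=pid, label=label, fall_dates=tuple(day(f) for f in falls)
    )


def record(pid: str, d: int, tokens=("alpha", "beta"), chars: int | None = None, **kw) -> NursingRecord:
    toks = tuple(tokens)
    return NursingRecord(
        patient_id=pid,
        date=day(d),
        tokens=toks,
        char_count=sum(len(t) for t in toks) if chars is None else chars,
        **kw,
    )


def make_corpus(patients, records) -> Corpus:
    return Corpus(patients={p.patient_id: p for p in patients}, records=list(records))


@pytest.fixture
def tiny_corpus() -> Corpus:
    """Two patients (one faller with a fall on day 10), four records."""
    return make_corpus(
        [patient("F1", "faller", falls=(10,)), patient("N1")],
        [
            record("F1", 3, tokens=("gait", "unsteady", "assist")),
            record("F1", 9, tokens=("dizzy", "night")),
            record("N1", 2, tokens=("stable", "walk")),
            record("N1", 5, tokens=("discharge", "plan")),
        ],
    )
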