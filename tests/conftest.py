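import datetime as dt

import pandas as pd
import pytest

from ehrwas.io import from_coded_events, from_patient_records
from ehrwas.types import CodedEvent, CodeList, PatientRecord, StudyConfig


def patient(pid, sex="F", birth=1940, start="1995-01-01", end="2012-01-01",
            death=None):
    return PatientRecord(
        patient_id=pid, sex=sex, birth_year=birth,
        reg_start=dt.date.fromisoformat(start),
        reg_end=dt.date.fromisoformat(end),
        death_date=dt.date.fromisoformat(death) if death else None,
    )


def event(pid, date, code, setting="secondary"):
    vocab = "ICD10" if setting == "secondary" else "READ2"
    return CodedEvent(patient_id=pid, event_date=dt.date.fromisoformat(date),
                      code=code, vocabulary=vocab, setting=setting)


def patients_frame(*records):
    return from_patient_records(records)


def events_frame(*evts):
    return from_coded_events(evts)


@pytest.fixture
def af_codes():
    from ehrwas.phenotypes import load_af_codes
    return load_af_codes()


@pytest.fixture
def config():
    return StudyConfig(rng_seed=7)


@pytest.fixture
def toy_cohort():
    """Three matched pairs with a handful of events around index 2005-06-01."""
    pats = patients_frame(
        patient("c1"), patient("c2"), patient("c3"),
        patient("k1"), patient("k2"), patient("k3"),
    )
    pairs = pd.DataFrame({
        "pair_id": [0, 1, 2],
        "case_id": ["c1", "c2", "c3"],
        "control_id": ["k1", "k2", "k3"],
        "index_date": pd.to_datetime(["2005-06-01"] * 3),
        "sex": ["F"] * 3,
        "case_birth_year": [1940] * 3,
        "control_birth_year": [1940] * 3,
        "age_difference_years": [0] * 3,
    })
    events = events_frame(
        # c1: three pre-index hospitalisations with the same code -> counts once
        event("c1", "2004-01-01", "I50.9"),
        event("c1", "2004-02-01", "I50.9"),
        event("c1", "2004-03-01", "I50.9"),
        event("c2", "1999-12-31", "I50.9"),   # > 5y before index: out of window
        event("c2", "2006-01-01", "C34.1"),
        event("c3", "2005-06-01", "I50.9"),   # index day: not counted
        event("k1", "2007-05-05", "I50.9"),
        event("k3", "2004-05-05", "I50.9"),   # pre-window control carrier
        event("k2", "2002-01-01", "K29.0"),   # control-only code
        event("c1", "2004-08-01", "G573.00", setting="primary"),  # AF: excluded
        event("c2", "2004-09-09", "H33..00", setting="primary"),
    )
    return pats, pairs, events
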