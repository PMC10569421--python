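"""Readers and writers for the delimited-text interchange formats.

Schemas (comma-separated, ISO-8601 dates):

* patients: ``patient_id,sex,birth_year,reg_start,reg_end,death_date``
  (empty ``death_date`` means alive at end of follow-up)
* events:   ``patient_id,event_date,code,vocabulary,setting``
* code lists: ``code,vocabulary``
* ranked results: ``stratum,rank,code,vocabulary,label,n_case,n_control,
  pct_case,pct_control,freq_ratio,ci_low,ci_high,disease_group,
  zero_control_flag``

Readers return pandas DataFrames with validated, canonically ordered content;
``to_patient_records`` / ``to_coded_events`` convert rows into the dataclass
types of :mod:`ehrwas.types`.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Iterable, List, Union

import numpy as np
import pandas as pd

from .types import (
    SETTING_VOCABULARY,
    SETTINGS,
    SEXES,
    VOCABULARIES,
    CodeList,
    CodedEvent,
    PatientRecord,
    normalize_icd10,
)

PathLike = Union[str, Path]

PATIENT_COLUMNS = ["patient_id", "sex", "birth_year", "reg_start", "reg_end", "death_date"]
EVENT_COLUMNS = ["patient_id", "event_date", "code", "vocabulary", "setting"]
RESULT_COLUMNS = [
    "stratum", "rank", "code", "vocabulary", "label", "n_case", "n_control",
    "pct_case", "pct_control", "freq_ratio", "ci_low", "ci_high",
    "disease_group", "zero_control_flag",
]


class ParseError(ValueError):
    """A malformed row in an input file; the message names the row."""


def _fail(path, row: int, msg: str):
    # row is the 1-based data row number (header excluded)
    raise ParseError(f"{path}: row {row}: {msg}")


def _parse_dates(frame: pd.DataFrame, column: str, path, required: bool) -> pd.Series:
    raw = frame[column].astype("string")
    blank = raw.isna() | (raw.str.strip() == "")
    parsed = pd.to_datetime(raw.where(~blank), format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & ~blank
    if required:
        bad = bad | blank
    if bad.any():
        _fail(path, int(np.flatnonzero(bad.to_numpy())[0]) + 1,
              f"malformed {column} {raw[bad].iloc[0]!r}")
    return parsed


def read_patients(path: PathLike) -> pd.DataFrame:
    """Read a patient registry table, validating every row."""
    frame = pd.read_csv(path, dtype="string", keep_default_na=False, na_values=[""])
    missing = set(PATIENT_COLUMNS) - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    frame = frame[PATIENT_COLUMNS].copy()

    bad_sex = ~frame["sex"].isin(SEXES)
    if bad_sex.any():
        _fail(path, int(np.flatnonzero(bad_sex.to_numpy())[0]) + 1,
              f"unknown sex {frame['sex'][bad_sex].iloc[0]!r}")
    birth = pd.to_numeric(frame["birth_year"], errors="coerce")
    bad_birth = birth.isna() | (birth < 1880) | (birth > 2016)
    if bad_birth.any():
        _fail(path, int(np.flatnonzero(bad_birth.to_numpy())[0]) + 1,
              f"implausible birth_year {frame['birth_year'][bad_birth].iloc[0]!r}")
    out = pd.DataFrame({
        "patient_id": frame["patient_id"].astype(str),
        "sex": frame["sex"].astype(str),
        "birth_year": birth.astype(int),
        "reg_start": _parse_dates(frame, "reg_start", path, required=True),
        "reg_end": _parse_dates(frame, "reg_end", path, required=True),
        "death_date": _parse_dates(frame, "death_date", path, required=False),
    })
    bad_interval = ~(out["reg_start"] < out["reg_end"])
    if bad_interval.any():
        _fail(path, int(np.flatnonzero(bad_interval.to_numpy())[0]) + 1,
              "reg_start must precede reg_end")
    bad_death = out["death_date"].notna() & (out["death_date"] < out["reg_start"])
    if bad_death.any():
        _fail(path, int(np.flatnonzero(bad_death.to_numpy())[0]) + 1,
              "death_date before reg_start")
    dup = out["patient_id"].duplicated()
    if dup.any():
        _fail(path, int(np.flatnonzero(dup.to_numpy())[0]) + 1,
              f"duplicate patient_id {out['patient_id'][dup].iloc[0]!r}")
    return out.sort_values("patient_id", kind="stable").reset_index(drop=True)


def write_patients(frame: pd.DataFrame, path: PathLike) -> None:
    out = frame.copy()
    for col in ("reg_start", "reg_end", "death_date"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out["death_date"] = out["death_date"].fillna("")
    out[PATIENT_COLUMNS].to_csv(path, index=False)


def canonical_event_order(frame: pd.DataFrame) -> pd.DataFrame:
    """Sort events on all columns so output never depends on storage order."""
    return frame.sort_values(
        ["patient_id", "event_date", "setting", "vocabulary", "code"],
        kind="stable",
    ).reset_index(drop=True)


def read_events(path: PathLike) -> pd.DataFrame:
    """Read a coded-event table; ICD-10 codes are normalised to dotted form."""
    frame = pd.read_csv(path, dtype="string", keep_default_na=False, na_values=[""])
    missing = set(EVENT_COLUMNS) - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    frame = frame[EVENT_COLUMNS].copy()
    return validate_events(pd.DataFrame({
        "patient_id": frame["patient_id"].astype(str),
        "event_date": _parse_dates(frame, "event_date", path, required=True),
        "code": frame["code"].astype(str),
        "vocabulary": frame["vocabulary"].astype(str),
        "setting": frame["setting"].astype(str),
    }), source=path)


def validate_events(frame: pd.DataFrame, source="events") -> pd.DataFrame:
    """Enforce event invariants and return the canonically ordered frame."""
    empty = frame["code"].str.len() == 0
    if empty.any():
        _fail(source, int(np.flatnonzero(empty.to_numpy())[0]) + 1, "empty code")
    bad_setting = ~frame["setting"].isin(SETTINGS)
    if bad_setting.any():
        _fail(source, int(np.flatnonzero(bad_setting.to_numpy())[0]) + 1,
              f"unknown setting {frame['setting'][bad_setting].iloc[0]!r}")
    bad_vocab = ~frame["vocabulary"].isin(VOCABULARIES)
    if bad_vocab.any():
        _fail(source, int(np.flatnonzero(bad_vocab.to_numpy())[0]) + 1,
              f"unknown vocabulary {frame['vocabulary'][bad_vocab].iloc[0]!r}")
    expected = frame["setting"].map(SETTING_VOCABULARY)
    mismatch = frame["vocabulary"] != expected
    if mismatch.any():
        i = int(np.flatnonzero(mismatch.to_numpy())[0])
        _fail(source, i + 1,
              f"setting={frame['setting'].iloc[i]} requires vocabulary="
              f"{expected.iloc[i]}, got {frame['vocabulary'].iloc[i]}")
    frame = frame.copy()
    is_icd = frame["vocabulary"] == "ICD10"
    frame.loc[is_icd, "code"] = frame.loc[is_icd, "code"].map(normalize_icd10)
    return canonical_event_order(frame)


def write_events(frame: pd.DataFrame, path: PathLike) -> None:
    out = frame.copy()
    out["event_date"] = pd.to_datetime(out["event_date"]).dt.strftime("%Y-%m-%d")
    out[EVENT_COLUMNS].to_csv(path, index=False)


def read_code_list(path: PathLike, name: str = "", description: str = "") -> CodeList:
    frame = pd.read_csv(path, dtype="string", keep_default_na=False, na_values=[""])
    entries = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        code, vocab = str(row.code), str(row.vocabulary)
        if vocab not in VOCABULARIES:
            _fail(path, i, f"unknown vocabulary {vocab!r}")
        if vocab == "ICD10":
            code = normalize_icd10(code)
        entries.append((code, vocab))
    if len(set(entries)) != len(entries):
        raise ParseError(f"{path}: duplicate (code, vocabulary) pairs")
    return CodeList(name=name or Path(path).stem, entries=frozenset(entries),
                    description=description)


def write_results(frame: pd.DataFrame, path: PathLike) -> None:
    """Write a ranked result table with stable float formatting."""
    frame[RESULT_COLUMNS].to_csv(path, index=False, float_format="%.6g")


def read_results(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# dataclass converters

def to_patient_records(frame: pd.DataFrame) -> List[PatientRecord]:
    records = []
    for row in frame.itertuples(index=False):
        death = None if pd.isna(row.death_date) else row.death_date.date()
        records.append(PatientRecord(
            patient_id=row.patient_id, sex=row.sex, birth_year=int(row.birth_year),
            reg_start=row.reg_start.date(), reg_end=row.reg_end.date(),
            death_date=death,
        ))
    return records


def from_patient_records(records: Iterable[PatientRecord]) -> pd.DataFrame:
    rows = [(r.patient_id, r.sex, r.birth_year, r.reg_start, r.reg_end, r.death_date)
            for r in records]
    frame = pd.DataFrame(rows, columns=PATIENT_COLUMNS)
    for col in ("reg_start", "reg_end", "death_date"):
        frame[col] = pd.to_datetime(frame[col])
    return frame


def to_coded_events(frame: pd.DataFrame) -> List[CodedEvent]:
    return [
        CodedEvent(patient_id=row.patient_id, event_date=row.event_date.date(),
                   code=row.code, vocabulary=row.vocabulary, setting=row.setting)
        for row in frame.itertuples(index=False)
    ]


def from_coded_events(events: Iterable[CodedEvent]) -> pd.DataFrame:
    rows = [(e.patient_id, e.event_date, e.code, e.vocabulary, e.setting)
            for e in events]
    frame = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    frame["event_date"] = pd.to_datetime(frame["event_date"])
    return canonical_event_order(frame)


def _as_date(value) -> dt.date:
    if isinstance(value, dt.date) and not isinstance(value, dt.datetime):
        return value
    return pd.Timestamp(value).date()
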