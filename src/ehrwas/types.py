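"""Domain record types and the study configuration.

The canonical in-memory containers for bulk data are pandas DataFrames with
the schemas documented in :mod:`ehrwas.io`; the dataclasses here define and
validate the shape of a single row and are what the converters in
:mod:`ehrwas.io` produce and consume.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, fields
from typing import Optional

SEXES = ("F", "M")
VOCABULARIES = ("ICD10", "READ2")
SETTINGS = ("primary", "secondary")
PERIODS = ("pre", "post")

#: Care setting implied for each vocabulary: hospital primary diagnoses are
#: ICD-10, general-practice records are Read v2.
SETTING_VOCABULARY = {"secondary": "ICD10", "primary": "READ2"}


def normalize_icd10(code: str) -> str:
    """Return an ICD-10 code in dotted form.

    Hospital extracts variously print ``I635`` or ``I63.5``; both normalise to
    ``I63.5``. Three-character codes (``C56``) are returned unchanged.
    """
    code = code.strip().upper()
    if "." in code or len(code) <= 3:
        return code
    return code[:3] + "." + code[3:]


@dataclass(frozen=True)
class PatientRecord:
    """One registrant: demographics plus the registration interval."""

    patient_id: str
    sex: str
    birth_year: int
    reg_start: dt.date
    reg_end: dt.date
    death_date: Optional[dt.date] = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not 1880 <= self.birth_year <= 2016:
            raise ValueError(f"implausible birth_year {self.birth_year}")
        if not self.reg_start < self.reg_end:
            raise ValueError("reg_start must precede reg_end")
        if self.death_date is not None and self.death_date < self.reg_start:
            raise ValueError("death_date before reg_start")


@dataclass(frozen=True)
class CodedEvent:
    """One dated clinical code with its vocabulary and care setting."""

    patient_id: str
    event_date: dt.date
    code: str
    vocabulary: str
    setting: str

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("code must be non-empty")
        if self.setting not in SETTINGS:
            raise ValueError(f"setting must be one of {SETTINGS}")
        if self.vocabulary not in VOCABULARIES:
            raise ValueError(f"vocabulary must be one of {VOCABULARIES}")
        expected = SETTING_VOCABULARY[self.setting]
        if self.vocabulary != expected:
            raise ValueError(
                f"setting={self.setting} requires vocabulary={expected}, "
                f"got {self.vocabulary}"
            )


@dataclass(frozen=True)
class CodeList:
    """A named phenotype: a set of (code, vocabulary) pairs."""

    name: str
    entries: frozenset  # of (code, vocabulary) tuples
    description: str = ""

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("code list must be non-empty")
        for code, vocab in self.entries:
            if not code:
                raise ValueError("empty code in code list")
            if vocab not in VOCABULARIES:
                raise ValueError(f"unknown vocabulary {vocab!r}")

    def icd10_prefixes(self) -> tuple:
        return tuple(sorted(c for c, v in self.entries if v == "ICD10"))

    def read_codes(self) -> frozenset:
        return frozenset(c for c, v in self.entries if v == "READ2")


@dataclass(frozen=True)
class StratumKey:
    """One of the four analysis cells: care setting x pre/post period."""

    setting: str
    period: str

    def __post_init__(self) -> None:
        if self.setting not in SETTINGS:
            raise ValueError(f"setting must be one of {SETTINGS}")
        if self.period not in PERIODS:
            raise ValueError(f"period must be one of {PERIODS}")

    def __str__(self) -> str:  # used in file names and result tables
        return f"{self.setting}_{self.period}"


ALL_STRATA = tuple(
    StratumKey(s, p) for s in SETTINGS for p in PERIODS
)


@dataclass
class StudyConfig:
    """Every tunable parameter of the scan.

    Defaults follow the study design: UK study period 1998-01-01 to
    2016-05-31, adults registered for at least one year, five-year windows
    either side of the index date, the leading 100 conditions, and 2,000
    balanced-bootstrap replicates.
    """

    study_start: dt.date = dt.date(1998, 1, 1)
    study_end: dt.date = dt.date(2016, 5, 31)
    min_age: int = 18
    min_registration_years: float = 1.0
    window_years: float = 5.0
    top_n: int = 100
    bootstrap_B: int = 2000
    ci_level: float = 0.95
    min_case_patients: int = 5
    age_match_tolerance_years: int = 0
    match_ratio: int = 1
    continuity_correction: float = 0.5
    rng_seed: int = 0
    count_mode: str = "patient"  # "patient" (default) or "visit"

    def __post_init__(self) -> None:
        if isinstance(self.study_start, str):
            self.study_start = dt.date.fromisoformat(self.study_start)
        if isinstance(self.study_end, str):
            self.study_end = dt.date.fromisoformat(self.study_end)
        if not self.study_start < self.study_end:
            raise ValueError("study_start must precede study_end")
        if self.window_years <= 0:
            raise ValueError("window_years must be positive")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.bootstrap_B < 2:
            raise ValueError("bootstrap_B must be >= 2")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.count_mode not in ("patient", "visit"):
            raise ValueError("count_mode must be 'patient' or 'visit'")

    @property
    def window_days(self) -> int:
        """Window length in whole days (365.25 days per year)."""
        return round(self.window_years * 365.25)

    @property
    def min_registration_days(self) -> int:
        return round(self.min_registration_years * 365.25)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown StudyConfig keys: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class IndexedCase:
    """An incident AF case: patient plus the date of the first AF code."""

    patient_id: str
    index_date: dt.date


@dataclass(frozen=True)
class MatchedPair:
    """A case and its risk-set sampled control sharing an index date."""

    case_id: str
    control_id: str
    index_date: dt.date
    sex: str
    age_difference_years: int = 0

    def __post_init__(self) -> None:
        if self.case_id == self.control_id:
            raise ValueError("case and control must differ")
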