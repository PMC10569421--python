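"""Classification of condition codes into the 14 disease groups.

Hospital (ICD-10) codes are classified by ordered rules: exact per-code
overrides first, then the longest matching three-character block prefix;
anything unmatched falls into "other". Primary-care conditions in the
packaged reference lists are free-text Read terms without codes and are
classified through an explicit normalised term -> group table. The cardiac
group carries an optional subcategory (arrhythmia, heart failure, heart
valve disease, cardiomyopathy, ischaemic heart disease, other).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .types import normalize_icd10

logger = logging.getLogger(__name__)

#: Canonical group identifiers, in a fixed order.
GROUPS = (
    "cardiac", "cerebrovascular", "vascular", "bleeding", "infection",
    "cancer", "respiratory", "endocrine", "gastrointestinal", "renal",
    "haematological", "osteoarticular", "frailty", "other",
)

GROUP_LABELS = {
    "cardiac": "Cardiac-related",
    "cerebrovascular": "Cerebrovascular",
    "vascular": "Peripheral or other vascular",
    "bleeding": "Bleeding/haemorrhagic",
    "infection": "Infection",
    "cancer": "Cancer",
    "respiratory": "Respiratory",
    "endocrine": "Endocrine, nutritional or metabolic",
    "gastrointestinal": "Gastrointestinal",
    "renal": "Renal",
    "haematological": "Haematological",
    "osteoarticular": "Osteoarticular & muscular",
    "frailty": "Frailty or multimorbidity",
    "other": "Other",
}

CARDIAC_SUBGROUPS = {
    "a": "arrhythmia",
    "b": "heart failure",
    "c": "heart valve disease",
    "d": "cardiomyopathy",
    "e": "ischaemic heart disease",
    "f": "other",
}


@dataclass(frozen=True)
class GroupRule:
    pattern: str       # exact code or code prefix
    vocabulary: str
    kind: str          # "exact" or "prefix"
    group: str
    subgroup: str = ""


@dataclass
class GroupScheme:
    """The 14-group classification scheme."""

    groups: Tuple[str, ...] = GROUPS
    rules: Sequence[GroupRule] = field(default_factory=tuple)
    term_overrides: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.groups) != 14:
            raise ValueError("scheme must define exactly 14 groups")
        for rule in self.rules:
            if rule.group not in self.groups:
                raise ValueError(f"rule group {rule.group!r} not in scheme")


_warned_codes: set = set()  # unmatched codes already warned about


def normalize_term(term: str) -> str:
    """Canonical form of a free-text condition term for table lookups."""
    term = term.lower().strip()
    term = re.sub(r"[^a-z0-9]+", " ", term)
    return re.sub(r"\s+", " ", term).strip()


def classify_code(code: str, vocabulary: str, scheme: GroupScheme,
                  with_subgroup: bool = False):
    """Group of one code: exact override first, then longest prefix rule.

    Compound printed codes ("I50.0/I50.1") are classified by their first
    token. Unmatched codes map to "other" with a logged warning.
    """
    code = code.split("/")[0].strip()
    if vocabulary == "ICD10":
        code = normalize_icd10(code)
    best: Optional[GroupRule] = None
    for rule in scheme.rules:
        if rule.vocabulary != vocabulary:
            continue
        if rule.kind == "exact" and rule.pattern == code:
            best = rule
            break
        if rule.kind == "prefix" and code.startswith(rule.pattern):
            if best is None or best.kind != "exact":
                if best is None or len(rule.pattern) > len(best.pattern):
                    best = rule
    if best is None:
        if (code, vocabulary) not in _warned_codes:
            _warned_codes.add((code, vocabulary))
            logger.warning("code %s (%s) matched no grouping rule; using 'other'",
                           code, vocabulary)
        return ("other", "") if with_subgroup else "other"
    if with_subgroup:
        return best.group, CARDIAC_SUBGROUPS.get(best.subgroup, best.subgroup)
    return best.group


def classify_term(term: str, scheme: GroupScheme) -> str:
    """Group of a free-text primary-care condition term."""
    group = scheme.term_overrides.get(normalize_term(term))
    if group is None:
        logger.warning("term %r not in term table; using 'other'", term)
        return "other"
    return group


def classify_entry(code: str, vocabulary: str, label: str,
                   scheme: GroupScheme) -> str:
    """Classify by code when one is present, otherwise by term."""
    if code and vocabulary == "ICD10":
        return classify_code(code, vocabulary, scheme)
    if label and normalize_term(label) in scheme.term_overrides:
        return classify_term(label, scheme)
    if code:
        return classify_code(code, vocabulary, scheme)
    return "other"


def group_counts(entries: pd.DataFrame, scheme: GroupScheme) -> pd.Series:
    """Per-group condition counts of a ranked list or reference fixture.

    ``entries`` needs ``code``, ``vocabulary`` and ``label`` columns (code may
    be empty for term-only rows). Counts sum to the number of entries; groups
    absent from the list report 0.
    """
    assigned = [
        classify_entry(str(row.code) if pd.notna(row.code) else "",
                       str(row.vocabulary) if pd.notna(row.vocabulary) else "",
                       str(row.label) if pd.notna(row.label) else "", scheme)
        for row in entries.itertuples(index=False)
    ]
    counts = pd.Series(assigned).value_counts()
    return counts.reindex(scheme.groups, fill_value=0).astype(int)


# ---------------------------------------------------------------------------
# shipped resources

def _read_resource(name: str) -> pd.DataFrame:
    path = resources.files("ehrwas.data").joinpath(name)
    with resources.as_file(path) as p:
        return pd.read_csv(p, dtype="string", keep_default_na=False)


def load_default_scheme() -> GroupScheme:
    """The shipped scheme: ICD-10 block prefix rules plus per-code overrides,
    with the primary-care term table derived from the reference lists."""
    rules_frame = _read_resource("disease_groups.csv")
    rules = tuple(
        GroupRule(pattern=str(r.pattern), vocabulary=str(r.vocabulary),
                  kind=str(r.kind), group=str(r.group),
                  subgroup=str(r.subgroup))
        for r in rules_frame.itertuples(index=False)
    )
    terms = _read_resource("term_groups.csv")
    overrides = {str(t.term): str(t.group) for t in terms.itertuples(index=False)}
    return GroupScheme(rules=rules, term_overrides=overrides)


def load_reference_tables() -> pd.DataFrame:
    """The packaged leading-100 reference lists (four strata x 100 entries).

    Columns: period (pre/post), setting (primary/secondary), rank, label,
    code (empty for primary-care term entries), vocabulary, group.
    """
    frame = _read_resource("paper_tables.csv")
    frame["rank"] = frame["rank"].astype(int)
    return frame


def load_novel_conditions() -> List[str]:
    """The ten conditions reported as not previously associated with AF."""
    frame = _read_resource("novel_conditions.csv")
    return [str(x) for x in frame["condition"]]


def load_fixture_exceptions() -> pd.DataFrame:
    """Reference-list entries whose printed group the scheme cannot reproduce."""
    return _read_resource("fixture_exceptions.csv")
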