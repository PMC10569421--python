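"""Cohort eligibility, incident-case identification and risk-set matching.

Eligibility follows the cohort design: adults (>= min_age at study entry)
registered for at least ``min_registration_years`` whose registration
overlaps the study period, excluding anyone with an AF code before their
study entry. Study entry is the later of registration start plus the minimum
registration time and the study start; exit is the earliest of registration
end, death and study end.

Controls are drawn by incidence-density (risk-set) sampling: for each case,
taken in ascending index-date order, controls are sampled uniformly without
replacement from patients of the same sex and birth year (within tolerance)
who are under observation and AF-free at the case's index date. A sampled
control keeps the case's index date; a patient who later develops AF can
serve as a control before their own onset, but no patient is used as a
control twice.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .phenotypes import first_af_dates
from .types import CodeList, StudyConfig

logger = logging.getLogger(__name__)

PAIR_COLUMNS = ["pair_id", "case_id", "control_id", "index_date", "sex",
                "case_birth_year", "control_birth_year", "age_difference_years"]


def _day_numbers(series: pd.Series) -> np.ndarray:
    return (series.astype("datetime64[ns]").to_numpy()
            .astype("datetime64[D]").astype("int64"))


def apply_eligibility(patients: pd.DataFrame, events: pd.DataFrame,
                      af_codes: CodeList, config: StudyConfig) -> pd.DataFrame:
    """Return eligible patients with their entry_date and exit_date columns."""
    out = patients.copy()
    entry = np.maximum(
        _day_numbers(out["reg_start"]) + config.min_registration_days,
        _day_numbers(pd.Series([pd.Timestamp(config.study_start)] * len(out))),
    )
    exit_day = np.minimum(
        _day_numbers(out["reg_end"]),
        pd.Timestamp(config.study_end).to_datetime64()
        .astype("datetime64[D]").astype("int64"),
    )
    death = _day_numbers(out["death_date"])
    has_death = out["death_date"].notna().to_numpy()
    exit_day = np.where(has_death, np.minimum(exit_day, death), exit_day)

    entry_year = pd.to_datetime(entry, unit="D").year.to_numpy()
    age_at_entry = entry_year - out["birth_year"].to_numpy()

    keep = (entry <= exit_day) & (age_at_entry >= config.min_age)

    first_af = first_af_dates(events, af_codes)
    af_day = out["patient_id"].map(first_af)
    has_af = af_day.notna().to_numpy()
    af_day_num = _day_numbers(af_day)
    prior_af = has_af & (af_day_num < entry)
    keep &= ~prior_af

    out["entry_date"] = pd.to_datetime(entry, unit="D")
    out["exit_date"] = pd.to_datetime(exit_day, unit="D")
    out = out.loc[keep].sort_values("patient_id", kind="stable")
    logger.info("eligibility: %d of %d patients eligible", len(out), len(patients))
    return out.reset_index(drop=True)


def identify_cases(eligible: pd.DataFrame, events: pd.DataFrame,
                   af_codes: CodeList, config: StudyConfig) -> pd.DataFrame:
    """Incident AF cases: earliest AF code within [entry, exit] per patient."""
    first_af = first_af_dates(events, af_codes)
    frame = eligible[["patient_id", "entry_date", "exit_date"]].copy()
    frame["index_date"] = frame["patient_id"].map(first_af)
    is_case = (frame["index_date"].notna()
               & (frame["index_date"] >= frame["entry_date"])
               & (frame["index_date"] <= frame["exit_date"]))
    cases = (frame.loc[is_case, ["patient_id", "index_date"]]
             .sort_values(["index_date", "patient_id"], kind="stable")
             .reset_index(drop=True))
    logger.info("cases: %d incident AF cases identified", len(cases))
    return cases


def match_controls(cases: pd.DataFrame, eligible: pd.DataFrame,
                   events: pd.DataFrame, af_codes: CodeList,
                   config: StudyConfig,
                   rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Incidence-density matching of controls to cases.

    Cases are processed in ascending (index_date, patient_id) order; for each,
    ``config.match_ratio`` controls are sampled uniformly (seeded) without
    replacement across the whole study from the case's risk set. Cases whose
    risk set is empty are dropped and logged.
    """
    if rng is None:
        rng = np.random.default_rng([int(config.rng_seed) % (2**31), 11])

    pool = eligible.sort_values("patient_id", kind="stable").reset_index(drop=True)
    ids = pool["patient_id"].to_numpy(dtype=object)
    sex = pool["sex"].to_numpy(dtype=object)
    birth = pool["birth_year"].to_numpy()
    entry = _day_numbers(pool["entry_date"])
    reg_end = _day_numbers(pool["reg_end"])
    study_end = (pd.Timestamp(config.study_end).to_datetime64()
                 .astype("datetime64[D]").astype("int64"))
    under_obs_end = np.minimum(reg_end, study_end)
    death = _day_numbers(pool["death_date"])
    has_death = pool["death_date"].notna().to_numpy()

    first_af = first_af_dates(events, af_codes)
    af_day = pool["patient_id"].map(first_af)
    has_af = af_day.notna().to_numpy()
    af_day_num = np.where(has_af, _day_numbers(af_day), np.iinfo("int64").max)

    id_to_pos = {pid: i for i, pid in enumerate(ids)}
    used = np.zeros(len(pool), dtype=bool)

    ordered = cases.sort_values(["index_date", "patient_id"], kind="stable")
    rows = []
    unmatched = 0
    pair_id = 0
    for case in ordered.itertuples(index=False):
        t = np.datetime64(case.index_date, "D").astype("int64")
        pos = id_to_pos.get(case.patient_id)
        case_birth = birth[pos] if pos is not None else None
        candidates = (
            (sex == (sex[pos] if pos is not None else None))
            & (np.abs(birth - case_birth) <= config.age_match_tolerance_years)
            & (entry <= t) & (t <= under_obs_end)
            & (~has_death | (death > t))
            & (af_day_num > t)
            & ~used
        )
        if pos is not None:
            candidates[pos] = False
        idx = np.flatnonzero(candidates)
        if len(idx) == 0:
            unmatched += 1
            logger.debug("case %s (index %s): empty risk set",
                         case.patient_id, case.index_date)
            continue
        k = min(config.match_ratio, len(idx))
        chosen = rng.choice(idx, size=k, replace=False)
        for c in np.sort(chosen):
            used[c] = True
            rows.append((pair_id, case.patient_id, ids[c], case.index_date,
                         sex[c], int(case_birth), int(birth[c]),
                         int(case_birth - birth[c])))
            pair_id += 1
    if unmatched:
        msg = "matching: %d of %d cases had an empty risk set and were dropped"
        if unmatched > 0.01 * max(len(ordered), 1):
            logger.warning(msg, unmatched, len(ordered))
        else:
            logger.info(msg, unmatched, len(ordered))
    pairs = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    if len(pairs):
        pairs["index_date"] = pd.to_datetime(pairs["index_date"])
    logger.info("matching: %d pairs formed from %d cases", len(pairs), len(ordered))
    return pairs
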