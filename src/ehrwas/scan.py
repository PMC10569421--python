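"""Windowed condition counting and frequency-ratio ranking.

The scan compares, separately in each of the four strata (primary/secondary
care x pre/post period), the share of case patients with at least one
qualifying code in the window against the same share among matched controls.
Windows are half-open around the index date: pre keeps
``index - W <= date < index``, post keeps ``index < date <= index + W``;
index-day events belong to neither, and the AF phenotype codes themselves are
excluded from scanned events. The frequency ratio is pct_case / pct_control,
with a continuity correction applied to both counts when the control count is
zero. An alternative visit-level counting mode (events rather than patients)
is available via ``StudyConfig.count_mode``.
"""

from __future__ import annotations

import datetime as dt
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .phenotypes import af_event_mask
from .types import ALL_STRATA, CodeList, StratumKey, StudyConfig

COUNT_COLUMNS = ["setting", "period", "code", "vocabulary",
                 "n_case", "n_control", "n_pairs", "pct_case", "pct_control"]


def window_events(events: pd.DataFrame, index_date, config: StudyConfig,
                  period: str, af_codes: Optional[CodeList] = None) -> pd.DataFrame:
    """Events of one window around ``index_date``.

    ``period='pre'`` keeps index - W <= date < index; ``'post'`` keeps
    index < date <= index + W. AF-phenotype events are dropped when a code
    list is given.
    """
    if period not in ("pre", "post"):
        raise ValueError("period must be 'pre' or 'post'")
    t = pd.Timestamp(index_date)
    w = pd.Timedelta(days=config.window_days)
    dates = events["event_date"]
    if period == "pre":
        mask = (dates >= t - w) & (dates < t)
    else:
        mask = (dates > t) & (dates <= t + w)
    if af_codes is not None:
        mask &= ~af_event_mask(events, af_codes)
    return events.loc[mask]


def pair_member_table(pairs: pd.DataFrame) -> pd.DataFrame:
    """One row per pair member: (pair_id, patient_id, role, index_date)."""
    case_rows = pairs[["pair_id", "case_id", "index_date"]].rename(
        columns={"case_id": "patient_id"})
    case_rows["role"] = "case"
    ctrl_rows = pairs[["pair_id", "control_id", "index_date"]].rename(
        columns={"control_id": "patient_id"})
    ctrl_rows["role"] = "control"
    return pd.concat([case_rows, ctrl_rows], ignore_index=True)


def windowed_pair_codes(pairs: pd.DataFrame, events: pd.DataFrame,
                        config: StudyConfig,
                        af_codes: Optional[CodeList] = None,
                        dedupe: bool = True) -> pd.DataFrame:
    """In-window events joined to pair members.

    Returns (pair_id, role, setting, period, code, vocabulary) rows; with
    ``dedupe`` (patient-level counting) each pair member contributes at most
    one row per (stratum, code) regardless of visit multiplicity.
    """
    members = pair_member_table(pairs)
    ev = events
    if af_codes is not None:
        ev = ev.loc[~af_event_mask(ev, af_codes)]
    merged = members.merge(ev, on="patient_id", how="inner")
    delta = (merged["event_date"] - merged["index_date"]).dt.days
    w = config.window_days
    pre = (delta >= -w) & (delta < 0)
    post = (delta > 0) & (delta <= w)
    merged = merged.loc[pre | post].copy()
    merged["period"] = np.where(
        (merged["event_date"] < merged["index_date"]), "pre", "post")
    cols = ["pair_id", "role", "setting", "period", "code", "vocabulary"]
    out = merged[cols]
    if dedupe:
        out = out.drop_duplicates()
    return out.reset_index(drop=True)


def count_conditions(pairs: pd.DataFrame, events: pd.DataFrame,
                     config: StudyConfig,
                     af_codes: Optional[CodeList] = None) -> pd.DataFrame:
    """Per-(stratum, code) case and control counts across matched pairs.

    In the default patient-level mode a pair member counts once per
    (stratum, code); in visit mode every in-window event counts. Codes with
    fewer than ``config.min_case_patients`` case carriers are dropped.
    """
    if pairs.empty:
        raise ValueError("no matched pairs to count over")
    n_pairs = len(pairs)
    table = windowed_pair_codes(pairs, events, config, af_codes,
                                dedupe=config.count_mode == "patient")
    grouped = (table.groupby(["setting", "period", "code", "vocabulary", "role"])
               .size().unstack("role", fill_value=0).reset_index())
    for col in ("case", "control"):
        if col not in grouped:
            grouped[col] = 0
    counts = grouped.rename(columns={"case": "n_case", "control": "n_control"})
    counts["n_pairs"] = n_pairs
    counts["pct_case"] = 100.0 * counts["n_case"] / n_pairs
    counts["pct_control"] = 100.0 * counts["n_control"] / n_pairs
    counts = counts.loc[counts["n_case"] >= config.min_case_patients]
    counts = counts.sort_values(["setting", "period", "code"], kind="stable")
    return counts[COUNT_COLUMNS].reset_index(drop=True)


def frequency_ratio(n_case: int, n_control: int, n_pairs: int,
                    config: StudyConfig):
    """Frequency ratio for one condition: pct_case / pct_control.

    When no control carries the code, the continuity correction ``c`` is
    added to both counts, giving (n_case + c) / c, and the zero-control flag
    is set. Undefined (raises) for a zero case count; such codes are filtered
    before ranking.
    """
    if n_case <= 0:
        raise ValueError("frequency ratio undefined for n_case = 0")
    if n_control > 0:
        return n_case / n_control, False
    c = config.continuity_correction
    return (n_case + c) / c, True


def add_frequency_ratios(counts: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Vectorised ``frequency_ratio`` over a count table."""
    if (counts["n_case"] <= 0).any():
        raise ValueError("frequency ratio undefined for n_case = 0")
    out = counts.copy()
    zero = out["n_control"] == 0
    c = config.continuity_correction
    out["freq_ratio"] = np.where(
        zero,
        (out["n_case"] + c) / c,
        out["n_case"] / out["n_control"].where(~zero, 1),
    )
    out["zero_control_flag"] = zero
    return out


def rank_leading(results: pd.DataFrame, config: StudyConfig
                 ) -> Dict[StratumKey, pd.DataFrame]:
    """Leading conditions per stratum, rank 1..min(top_n, available).

    Sort key: descending (freq_ratio, pct_case), then ascending code string —
    a deterministic total order.
    """
    ranked: Dict[StratumKey, pd.DataFrame] = {}
    for stratum in ALL_STRATA:
        sub = results.loc[(results["setting"] == stratum.setting)
                          & (results["period"] == stratum.period)].copy()
        sub = sub.sort_values(
            by=["freq_ratio", "pct_case", "code"],
            ascending=[False, False, True], kind="stable",
        ).head(config.top_n).reset_index(drop=True)
        sub.insert(0, "rank", np.arange(1, len(sub) + 1))
        ranked[stratum] = sub
    return ranked
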