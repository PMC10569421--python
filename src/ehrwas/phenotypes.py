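"""Phenotype code lists and event matching.

Atrial fibrillation is defined by ICD-10 I48 (prefix match, so I48.0, I48.1,
... all qualify) in hospital data and by an exact-match list of seven-character
Read v2 codes in primary care. The shipped AF list records the Read code
``3272.00`` in both its plain and comma-containing printed forms.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .io import read_code_list
from .types import CodeList


def _data_path(name: str):
    return resources.files("ehrwas.data").joinpath(name)


def load_af_codes() -> CodeList:
    """The shipped atrial-fibrillation phenotype code list."""
    with resources.as_file(_data_path("af_codes.csv")) as path:
        return read_code_list(
            path, name="atrial_fibrillation",
            description="ICD-10 I48 (prefix) and Read v2 AF codes (exact)",
        )


def af_event_mask(events: pd.DataFrame, af_codes: CodeList) -> np.ndarray:
    """Boolean mask of events matching the AF phenotype.

    ICD-10 entries match as code prefixes; Read entries match exactly.
    """
    codes = events["code"].to_numpy(dtype=object)
    vocab = events["vocabulary"].to_numpy(dtype=object)
    mask = np.zeros(len(events), dtype=bool)
    prefixes = af_codes.icd10_prefixes()
    if prefixes:
        icd = vocab == "ICD10"
        starts = events["code"].str.startswith(prefixes).to_numpy()
        mask |= icd & starts
    reads = af_codes.read_codes()
    if reads:
        mask |= (vocab == "READ2") & np.isin(codes, list(reads))
    return mask


def first_af_dates(events: pd.DataFrame, af_codes: CodeList) -> pd.Series:
    """Each patient's earliest AF-coded event date (patients without AF absent)."""
    af = events.loc[af_event_mask(events, af_codes)]
    if af.empty:
        return pd.Series(dtype="datetime64[ns]", name="first_af")
    return af.groupby("patient_id")["event_date"].min().rename("first_af")
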