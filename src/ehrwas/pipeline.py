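"""End-to-end orchestration: cohort -> matching -> scan -> CIs -> figure."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import bootstrap, cohort, scan
from .grouping import GroupScheme, classify_entry, load_default_scheme
from .io import RESULT_COLUMNS, write_results
from .iris_plot import render
from .phenotypes import load_af_codes
from .types import ALL_STRATA, CodeList, StratumKey, StudyConfig

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class ScanOutput:
    """Everything the pipeline produces."""

    tables: Dict[StratumKey, pd.DataFrame]
    cases: pd.DataFrame
    pairs: pd.DataFrame
    eligible_count: int
    figure_paths: Dict[str, Path] = field(default_factory=dict)


def run_pipeline(config: StudyConfig, patients: pd.DataFrame,
                 events: pd.DataFrame,
                 af_codes: Optional[CodeList] = None,
                 scheme: Optional[GroupScheme] = None,
                 label_map: Optional[Dict[str, str]] = None,
                 out_dir: Optional[str] = None,
                 make_figure: bool = True) -> ScanOutput:
    """Run the full association scan.

    Deterministic given ``config.rng_seed``; writes one ranked table per
    stratum plus the iris plot when ``out_dir`` is given. Raises
    :class:`PipelineError` when no matched pairs can be formed.
    """
    af_codes = af_codes or load_af_codes()
    scheme = scheme or load_default_scheme()
    label_map = label_map or {}

    eligible = cohort.apply_eligibility(patients, events, af_codes, config)
    cases = cohort.identify_cases(eligible, events, af_codes, config)
    pairs = cohort.match_controls(cases, eligible, events, af_codes, config)
    logger.info("pipeline: %d eligible, %d cases, %d matched pairs",
                len(eligible), len(cases), len(pairs))
    if pairs.empty:
        raise PipelineError(
            "no matched pairs could be formed (no qualifying AF cases or "
            "empty risk sets); refusing to produce empty output")

    counts = scan.count_conditions(pairs, events, config, af_codes)
    results = scan.add_frequency_ratios(counts, config)
    ranked = scan.rank_leading(results, config)

    wanted = {stratum: list(table["code"]) for stratum, table in ranked.items()}
    cis = bootstrap.bootstrap_cis(pairs, events, wanted, config, af_codes)

    tables: Dict[StratumKey, pd.DataFrame] = {}
    for stratum in ALL_STRATA:
        table = ranked[stratum].merge(
            cis.loc[(cis["setting"] == stratum.setting)
                    & (cis["period"] == stratum.period),
                    ["code", "ci_low", "ci_high"]],
            on="code", how="left")
        table["stratum"] = str(stratum)
        table["label"] = [label_map.get(c, c) for c in table["code"]]
        table["disease_group"] = [
            classify_entry(code, vocab, label, scheme)
            for code, vocab, label in zip(table["code"], table["vocabulary"],
                                          table["label"])
        ]
        tables[stratum] = table[RESULT_COLUMNS].reset_index(drop=True)

    output = ScanOutput(tables=tables, cases=cases, pairs=pairs,
                        eligible_count=len(eligible))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for stratum, table in tables.items():
            write_results(table, out / f"ranked_{stratum}.csv")
        if make_figure:
            output.figure_paths = render(tables, out / "iris", scheme)
    return output
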