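"""Frozen synthetic study scenarios.

These configurations define the simulation conditions used throughout the
package's validation studies — the ranking contract on a rich code universe,
the null-calibration study (all planted ratios one), and the
parameter-recovery study (one planted pre-window effect). Sizes are chosen to
be desk-scale while keeping every stratum well populated; the registration
windows of the calibration scenarios are placed early enough that the
five-year windows around in-study index dates are almost never truncated by
registration boundaries.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
import pandas as pd

from . import cohort
from .phenotypes import load_af_codes
from .synthetic import (CodeDef, SyntheticConfig, default_code_universe,
                        generate_af_onsets, generate_events,
                        generate_population)
from .types import StudyConfig

#: Planted code and effect of the recovery study.
RECOVERY_CODE = "R77.7"
RECOVERY_BASE_RATE = 0.08   # events per patient-year
RECOVERY_PRE_RATIO = 4.0


def ranking_scenario(seed: int) -> SyntheticConfig:
    """A cohort with >=150 qualifying codes per care setting."""
    return SyntheticConfig(
        n_patients=8000,
        af_annual_hazard=0.012,
        birth_year_range=(1925, 1970),
        registration_span_years=(20.0, 35.0),
        code_universe=default_code_universe(160, 160, rate_range=(0.03, 0.2)),
        rng_seed=seed,
    )


def null_scenario(seed: int, n_codes: int = 100) -> SyntheticConfig:
    """All planted ratios one: the scan's frequency ratios should centre at 1."""
    return SyntheticConfig(
        n_patients=3000,
        af_annual_hazard=0.015,
        birth_year_range=(1930, 1970),
        registration_span_years=(30.0, 45.0),
        registration_start_years=(1980, 1990),
        code_universe=default_code_universe(n_codes, 0, rate_range=(0.05, 0.3)),
        rng_seed=seed,
    )


def recovery_scenario(seed: int) -> SyntheticConfig:
    """One hospital code with a planted pre-window rate ratio of 4."""
    universe = (
        CodeDef(RECOVERY_CODE, "ICD10", "secondary", RECOVERY_BASE_RATE),
        CodeDef("J20.0", "ICD10", "secondary", 0.1),  # background noise code
    )
    return SyntheticConfig(
        n_patients=9000,
        af_annual_hazard=0.005,
        birth_year_range=(1930, 1970),
        registration_span_years=(26.0, 34.0),
        registration_start_years=(1985, 1992),
        code_universe=universe,
        planted_effects={RECOVERY_CODE: (RECOVERY_PRE_RATIO, 1.0)},
        rng_seed=seed,
    )


def simulate(cfg: SyntheticConfig):
    """Population, ground truth and events for a scenario config."""
    patients = generate_population(cfg)
    truth = generate_af_onsets(patients, cfg)
    events = generate_events(patients, truth, cfg)
    return patients, truth, events


def matched_pairs(cfg: SyntheticConfig, study: StudyConfig,
                  max_pairs: int | None = None
                  ) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a scenario and run it through eligibility, cases and matching.

    Returns (patients, events, pairs); pairs are truncated to ``max_pairs``
    in their deterministic (index date, case id) formation order when a fixed
    study size is wanted.
    """
    patients, truth, events = simulate(cfg)
    af = load_af_codes()
    eligible = cohort.apply_eligibility(patients, events, af, study)
    cases = cohort.identify_cases(eligible, events, af, study)
    pairs = cohort.match_controls(cases, eligible, events, af, study)
    if max_pairs is not None and len(pairs) > max_pairs:
        pairs = pairs.head(max_pairs).copy()
    return patients, events, pairs
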