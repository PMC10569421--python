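"""Balanced bootstrap over matched pairs with percentile confidence intervals.

The resampling unit is the matched pair, preserving the matched design. In a
balanced bootstrap the concatenation of all B replicates contains every pair
index exactly B times: the plan is built by concatenating B copies of
{0..n_pairs-1}, applying one seeded uniform permutation, and cutting the
result into B consecutive blocks of n_pairs slots. Each replicate recomputes
the case/control counts with pair multiplicities as weights; the confidence
interval is the percentile interval of the B replicate ratios, with endpoints
taken as exact order statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .scan import windowed_pair_codes
from .types import ALL_STRATA, CodeList, StratumKey, StudyConfig

CI_COLUMNS = ["setting", "period", "code", "vocabulary", "ci_low", "ci_high"]


@dataclass
class BootstrapPlan:
    """B replicates of n_pairs pair indices satisfying the balance property."""

    n_pairs: int
    B: int
    assignments: np.ndarray  # shape (B, n_pairs), dtype int
    seed: int

    def occurrence_counts(self) -> np.ndarray:
        """Total appearances of each pair index across all replicates."""
        return np.bincount(self.assignments.ravel(), minlength=self.n_pairs)

    def weights(self) -> np.ndarray:
        """(B, n_pairs) multiplicity matrix: draws of each pair per replicate."""
        w = np.zeros((self.B, self.n_pairs), dtype=np.int64)
        rows = np.repeat(np.arange(self.B), self.n_pairs)
        np.add.at(w, (rows, self.assignments.ravel()), 1)
        return w


def balanced_plan(n_pairs: int, B: int, seed: int) -> BootstrapPlan:
    """Construct a balanced bootstrap plan."""
    if n_pairs < 1 or B < 1:
        raise ValueError("n_pairs and B must be >= 1")
    rng = np.random.default_rng(seed)
    pool = np.tile(np.arange(n_pairs), B)
    rng.shuffle(pool)
    return BootstrapPlan(n_pairs=n_pairs, B=B,
                         assignments=pool.reshape(B, n_pairs), seed=seed)


def percentile_interval(values: np.ndarray, ci_level: float, axis: int = 0):
    """Percentile CI whose endpoints are order statistics of ``values``."""
    b = values.shape[axis]
    alpha = 1.0 - ci_level
    k_lo = min(max(int(math.floor(alpha / 2 * b)), 0), b - 1)
    k_hi = min(max(int(math.ceil((1 - alpha / 2) * b)) - 1, 0), b - 1)
    ordered = np.sort(values, axis=axis)
    lo = np.take(ordered, k_lo, axis=axis)
    hi = np.take(ordered, k_hi, axis=axis)
    return lo, hi


def replicate_ratios(case_present: np.ndarray, control_present: np.ndarray,
                     weights: np.ndarray, continuity: float) -> np.ndarray:
    """Frequency ratios of every replicate for one or more codes.

    ``case_present``/``control_present`` are (n_pairs, n_codes) carrier
    indicators (or visit counts in visit mode), ``weights`` the (B, n_pairs)
    multiplicity matrix. When a replicate draws a zero count in either arm
    the continuity correction is added to both.
    """
    n_case = weights @ case_present.astype(np.int64)
    n_control = weights @ control_present.astype(np.int64)
    zero = (n_case == 0) | (n_control == 0)
    ratios = np.where(
        zero,
        (n_case + continuity) / (n_control + continuity),
        n_case / np.where(zero, 1, n_control),
    )
    return ratios


def bootstrap_cis(pairs: pd.DataFrame, events: pd.DataFrame,
                  codes: Dict[StratumKey, Sequence[str]],
                  config: StudyConfig,
                  af_codes: Optional[CodeList] = None,
                  plan: Optional[BootstrapPlan] = None) -> pd.DataFrame:
    """Balanced-bootstrap CIs for the given codes in each stratum.

    ``codes`` maps each stratum to the codes (normally the ranked leading
    set) whose intervals are wanted. Deterministic given the study seed.
    """
    n_pairs = len(pairs)
    if n_pairs == 0:
        raise ValueError("no matched pairs")
    if plan is None:
        plan = balanced_plan(n_pairs, config.bootstrap_B,
                             seed=int(config.rng_seed) % (2**31) + 13)
    weights = plan.weights()

    table = windowed_pair_codes(pairs, events, config, af_codes,
                                dedupe=config.count_mode == "patient")
    pair_pos = {pid: i for i, pid in enumerate(pairs["pair_id"])}

    rows = []
    for stratum in ALL_STRATA:
        wanted = list(codes.get(stratum, []))
        if not wanted:
            continue
        sub = table.loc[(table["setting"] == stratum.setting)
                        & (table["period"] == stratum.period)
                        & table["code"].isin(wanted)]
        code_pos = {c: j for j, c in enumerate(wanted)}
        vocab = dict(zip(sub["code"], sub["vocabulary"]))
        case_p = np.zeros((n_pairs, len(wanted)), dtype=np.int64)
        ctrl_p = np.zeros((n_pairs, len(wanted)), dtype=np.int64)
        pi = sub["pair_id"].map(pair_pos).to_numpy(dtype=np.int64)
        cj = sub["code"].map(code_pos).to_numpy(dtype=np.int64)
        is_case = (sub["role"] == "case").to_numpy()
        np.add.at(case_p, (pi[is_case], cj[is_case]), 1)
        np.add.at(ctrl_p, (pi[~is_case], cj[~is_case]), 1)

        ratios = replicate_ratios(case_p, ctrl_p, weights,
                                  config.continuity_correction)
        lo, hi = percentile_interval(ratios, config.ci_level, axis=0)
        for j, code in enumerate(wanted):
            rows.append((stratum.setting, stratum.period, code,
                         vocab.get(code, ""), float(lo[j]), float(hi[j])))
    return pd.DataFrame(rows, columns=CI_COLUMNS)
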