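"""Synthetic coded-EHR generator with known ground truth.

Emulates a registered primary-care population over a fixed study period with
an atrial-fibrillation onset process and per-code homogeneous Poisson event
streams. Event rates for future cases are multiplied by configurable planted
ratios inside the pre- and post-onset windows, so the patient-level frequency
ratio the downstream scan should recover is known analytically
(:func:`implied_frequency_ratio`).

The generator emulates the study conditions, not the source database: no
correlated multimorbidity, no differential mortality, no calibration to
real-world code prevalences.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import EVENT_COLUMNS, PATIENT_COLUMNS, canonical_event_order
from .types import SETTING_VOCABULARY

DAYS_PER_YEAR = 365.25

#: ICD-10 code emitted at each simulated AF onset (hospital primary diagnosis).
AF_ONSET_CODE = "I48.9"


@dataclass(frozen=True)
class CodeDef:
    """One entry of the simulated code universe."""

    code: str
    vocabulary: str
    setting: str
    base_rate: float  # events per patient-year

    def __post_init__(self) -> None:
        if self.base_rate < 0:
            raise ValueError("base_rate must be >= 0")
        if SETTING_VOCABULARY.get(self.setting) != self.vocabulary:
            raise ValueError(
                f"setting {self.setting!r} incompatible with vocabulary "
                f"{self.vocabulary!r}"
            )


@dataclass
class SyntheticConfig:
    """Parameters of the simulated population and its event streams."""

    n_patients: int
    female_fraction: float = 0.5
    birth_year_range: Tuple[int, int] = (1930, 1975)
    registration_span_years: Tuple[float, float] = (15.0, 35.0)
    af_annual_hazard: float = 0.01
    code_universe: Sequence[CodeDef] = field(default_factory=tuple)
    planted_effects: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    window_years: float = 5.0
    study_start: dt.date = dt.date(1998, 1, 1)
    study_end: dt.date = dt.date(2016, 5, 31)
    min_adult_age: int = 18
    registration_start_years: Optional[Tuple[int, int]] = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not 0 <= self.female_fraction <= 1:
            raise ValueError("female_fraction must lie in [0, 1]")
        if self.af_annual_hazard < 0:
            raise ValueError("af_annual_hazard must be >= 0")
        if self.window_years <= 0:
            raise ValueError("window_years must be positive")
        for code, (pre, post) in self.planted_effects.items():
            if pre <= 0 or post <= 0:
                raise ValueError(f"planted ratios for {code!r} must be > 0")
        self.code_universe = tuple(self.code_universe)


@dataclass
class GroundTruth:
    """Planted truth: case onsets and the per-code rate multipliers."""

    onsets: pd.DataFrame  # columns: patient_id, onset_date
    planted_effects: Dict[str, Tuple[float, float]]
    config: SyntheticConfig

    @property
    def case_ids(self) -> List[str]:
        return list(self.onsets["patient_id"])

    def implied_ratio(self, code: str, period: str) -> float:
        """Analytic patient-level frequency ratio the scan should estimate."""
        rates = {c.code: c.base_rate for c in self.config.code_universe}
        pre, post = self.planted_effects.get(code, (1.0, 1.0))
        ratio = pre if period == "pre" else post
        return implied_frequency_ratio(rates[code], ratio,
                                       self.config.window_years)


def implied_frequency_ratio(base_rate: float, rate_ratio: float,
                            window_years: float) -> float:
    """Patient-level frequency ratio implied by a planted rate multiplier.

    With independent Poisson streams, the probability of at least one event in
    a full window of W years is 1 - exp(-rate * W); the ratio of these
    occurrence probabilities between cases (rate_ratio * base_rate) and
    controls (base_rate) is the estimand of the patient-level scan.
    """
    lam = base_rate * window_years
    return -math.expm1(-rate_ratio * lam) / -math.expm1(-lam)


# ---------------------------------------------------------------------------
# generation

_EPOCH = np.datetime64("1970-01-01")


def _to_day(date: dt.date) -> int:
    return (np.datetime64(date) - _EPOCH).astype(int)


def _rng(cfg: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.rng_seed) % (2**31), stream])


def generate_population(cfg: SyntheticConfig) -> pd.DataFrame:
    """Simulate the patient registry.

    Sexes are Bernoulli(female_fraction), birth years uniform in range, and
    registration intervals are placed to overlap the study period (uniform
    start over a range that guarantees at least two years of overlap, unless
    ``registration_start_years`` pins the start-year range explicitly).
    """
    rng = _rng(cfg, 1)
    n = cfg.n_patients
    sex = np.where(rng.random(n) < cfg.female_fraction, "F", "M")
    birth = rng.integers(cfg.birth_year_range[0], cfg.birth_year_range[1] + 1,
                         size=n)
    lo, hi = cfg.registration_span_years
    span_days = np.rint(rng.uniform(lo, hi, size=n) * DAYS_PER_YEAR).astype(int)
    span_days = np.maximum(span_days, 1)

    s0, s1 = _to_day(cfg.study_start), _to_day(cfg.study_end)
    if cfg.registration_start_years is not None:
        y0, y1 = cfg.registration_start_years
        start_lo = np.full(n, _to_day(dt.date(y0, 1, 1)))
        start_hi = np.full(n, _to_day(dt.date(y1, 12, 31)))
    else:
        overlap = np.minimum(span_days, int(2 * DAYS_PER_YEAR))
        start_lo = s0 - span_days + overlap
        start_hi = np.full(n, s1) - overlap
    start = np.floor(start_lo + rng.random(n) * (start_hi - start_lo + 1)).astype(int)
    end = start + span_days

    frame = pd.DataFrame({
        "patient_id": [f"p{i:07d}" for i in range(n)],
        "sex": sex,
        "birth_year": birth,
        "reg_start": pd.to_datetime(start, unit="D"),
        "reg_end": pd.to_datetime(end, unit="D"),
        "death_date": pd.Series([pd.NaT] * n, dtype="datetime64[ns]"),
    })
    return frame[PATIENT_COLUMNS]


def _risk_interval_days(patients: pd.DataFrame, cfg: SyntheticConfig):
    """Each patient's registered, in-study adult time as day numbers."""
    adult = np.array([
        _to_day(dt.date(int(y) + cfg.min_adult_age, 1, 1))
        for y in patients["birth_year"]
    ])
    start = np.maximum.reduce([
        patients["reg_start"].astype("datetime64[ns]").to_numpy()
        .astype("datetime64[D]").astype(int),
        np.full(len(patients), _to_day(cfg.study_start)),
        adult,
    ])
    end = np.minimum(
        patients["reg_end"].astype("datetime64[ns]").to_numpy()
        .astype("datetime64[D]").astype(int),
        _to_day(cfg.study_end),
    )
    return start, end


def generate_af_onsets(patients: pd.DataFrame, cfg: SyntheticConfig) -> GroundTruth:
    """Simulate first-AF onsets as a constant-hazard process over risk time."""
    rng = _rng(cfg, 2)
    start, end = _risk_interval_days(patients, cfg)
    at_risk_days = np.maximum(end - start, 0)
    u = rng.random(len(patients))
    if cfg.af_annual_hazard > 0:
        wait_days = -np.log(u) / (cfg.af_annual_hazard / DAYS_PER_YEAR)
    else:
        wait_days = np.full(len(patients), np.inf)
    onset_day = start + np.floor(wait_days)
    is_case = (at_risk_days > 0) & (onset_day <= end)
    onsets = pd.DataFrame({
        "patient_id": patients.loc[is_case, "patient_id"].to_numpy(),
        "onset_date": pd.to_datetime(onset_day[is_case].astype(int), unit="D"),
    }).reset_index(drop=True)
    return GroundTruth(onsets=onsets, planted_effects=dict(cfg.planted_effects),
                       config=cfg)


def _segment_events(rng, seg_start, seg_len, rate_per_day, patient_idx):
    """Draw Poisson event counts per segment and uniform day positions."""
    seg_len = np.maximum(seg_len, 0)
    counts = rng.poisson(rate_per_day * seg_len)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    starts = np.repeat(seg_start, counts)
    lens = np.repeat(seg_len, counts)
    pidx = np.repeat(patient_idx, counts)
    days = np.floor(starts + rng.random(total) * lens).astype(int)
    return pidx, days


def generate_events(patients: pd.DataFrame, truth: GroundTruth,
                    cfg: SyntheticConfig) -> pd.DataFrame:
    """Simulate per-(patient, code) Poisson event streams.

    For cases, the base rate of a planted code is multiplied by its pre-ratio
    on [onset - W, onset) and by its post-ratio on (onset, onset + W], both
    clipped to the registration interval; the index day itself stays at the
    base rate. Every case additionally receives one AF code at onset. All
    events fall inside [reg_start, reg_end].
    """
    rng = _rng(cfg, 3)
    n = len(patients)
    reg_start = (patients["reg_start"].astype("datetime64[ns]").to_numpy()
                 .astype("datetime64[D]").astype(int))
    reg_end = (patients["reg_end"].astype("datetime64[ns]").to_numpy()
               .astype("datetime64[D]").astype(int))

    onset_map = dict(zip(truth.onsets["patient_id"],
                         truth.onsets["onset_date"].astype("datetime64[ns]")
                         .to_numpy().astype("datetime64[D]").astype(int)))
    onset = np.array([onset_map.get(pid, -1) for pid in patients["patient_id"]])
    is_case = onset >= 0
    window = int(round(cfg.window_years * DAYS_PER_YEAR))
    idx_all = np.arange(n)

    frames = []
    for cdef in cfg.code_universe:
        if cdef.base_rate == 0:
            continue
        rate = cdef.base_rate / DAYS_PER_YEAR
        pre_ratio, post_ratio = truth.planted_effects.get(cdef.code, (1.0, 1.0))
        pidx_parts, day_parts = [], []

        if (pre_ratio, post_ratio) == (1.0, 1.0) or not is_case.any():
            p, d = _segment_events(rng, reg_start, reg_end - reg_start,
                                   np.full(n, rate), idx_all)
            pidx_parts.append(p); day_parts.append(d)
        else:
            # non-cases: one flat segment
            nc = ~is_case
            p, d = _segment_events(rng, reg_start[nc],
                                   reg_end[nc] - reg_start[nc],
                                   np.full(nc.sum(), rate), idx_all[nc])
            pidx_parts.append(p); day_parts.append(d)
            # cases: five segments around the onset day t
            a, b, t = reg_start[is_case], reg_end[is_case], onset[is_case]
            ci = idx_all[is_case]
            pre_lo = np.clip(t - window, a, b)
            pre_hi = np.clip(t, a, b)
            post_lo = np.clip(t + 1, a, b)
            post_hi = np.clip(t + 1 + window, a, b)
            for lo, hi, mult in (
                (a, pre_lo, 1.0),
                (pre_lo, pre_hi, pre_ratio),
                (pre_hi, post_lo, 1.0),          # the index day
                (post_lo, post_hi, post_ratio),
                (post_hi, b, 1.0),
            ):
                p, d = _segment_events(rng, lo, hi - lo,
                                       np.full(len(ci), rate * mult), ci)
                pidx_parts.append(p); day_parts.append(d)

        pidx = np.concatenate(pidx_parts)
        if len(pidx) == 0:
            continue
        days = np.concatenate(day_parts)
        frames.append(pd.DataFrame({
            "patient_id": patients["patient_id"].to_numpy()[pidx],
            "event_date": pd.to_datetime(days, unit="D"),
            "code": cdef.code,
            "vocabulary": cdef.vocabulary,
            "setting": cdef.setting,
        }))

    if is_case.any():
        frames.append(pd.DataFrame({
            "patient_id": patients["patient_id"].to_numpy()[is_case],
            "event_date": pd.to_datetime(onset[is_case].astype(int), unit="D"),
            "code": AF_ONSET_CODE,
            "vocabulary": "ICD10",
            "setting": "secondary",
        }))

    if not frames:
        return pd.DataFrame(columns=EVENT_COLUMNS).astype(
            {"event_date": "datetime64[ns]"})
    return canonical_event_order(pd.concat(frames, ignore_index=True))


def default_code_universe(n_secondary: int = 160, n_primary: int = 160,
                          rate_range: Tuple[float, float] = (0.02, 0.2),
                          seed: int = 7) -> Tuple[CodeDef, ...]:
    """A reproducible universe of plausible ICD-10-style and Read-style codes.

    Hospital codes span the common ICD-10 chapters (avoiding the AF block
    I48); primary-care codes are synthetic seven-character Read-style codes.
    Base rates are log-uniform over ``rate_range`` events per patient-year.
    """
    rng = np.random.default_rng(seed)
    letters = "ACDEFGIJKLMNR"
    codes = []
    seen = set()
    while len(codes) < n_secondary:
        letter = letters[rng.integers(len(letters))]
        num = int(rng.integers(0, 100))
        sub = int(rng.integers(0, 10))
        code = f"{letter}{num:02d}.{sub}"
        if code.startswith("I48") or code in seen:
            continue
        seen.add(code)
        codes.append(("secondary", "ICD10", code))
    while len(codes) < n_secondary + n_primary:
        letter = letters[rng.integers(len(letters))]
        num = int(rng.integers(0, 1000))
        code = f"{letter}{num:03d}.00"
        if code in seen:
            continue
        seen.add(code)
        codes.append(("primary", "READ2", code))
    log_lo, log_hi = np.log(rate_range[0]), np.log(rate_range[1])
    rates = np.exp(rng.uniform(log_lo, log_hi, size=len(codes)))
    return tuple(
        CodeDef(code=c, vocabulary=v, setting=s, base_rate=float(r))
        for (s, v, c), r in zip(codes, rates)
    )
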