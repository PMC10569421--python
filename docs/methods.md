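# Methods

This note records the statistical model, the choices the package makes where
the design was genuinely open, and what its validation studies do and do not
demonstrate.

## Design

The scan is a matched case-control comparison of coded healthcare contact
around incident atrial fibrillation. Its estimand, per condition code and per
stratum (care setting × pre/post period), is the ratio of patient-level
occurrence probabilities

FR = P(≥1 in-window event | case) / P(≥1 in-window event | matched control),

estimated by the ratio of observed carrier percentages among the matched
pairs. Counting patients rather than visits makes the statistic insensitive
to repeat-attendance behaviour of a few individuals; a visit-level mode
(`StudyConfig.count_mode="visit"`) is provided for sensitivity analysis and
changes both the point estimates and the bootstrap to weighted visit counts.
No multiple-testing adjustment is applied: conditions are ranked by the
magnitude of FR and uncertainty is reported as confidence intervals, in
keeping with the descriptive, hypothesis-generating intent of the design.

### Cohort and matching

Study entry is the later of (registration start + `min_registration_years`)
and the study start; exit the earliest of registration end, death and study
end. Eligibility requires adulthood at entry (age is computed from birth year
only, as `entry_year − birth_year`, the resolution the data model carries)
and no AF code before entry. The index date is the first qualifying AF code
within [entry, exit]; ICD-10 matching is prefix-based on `I48` so that all
fourth-character subdivisions qualify, while Read codes match exactly,
because the phenotype list enumerates terminal seven-character codes.

Controls are matched by incidence-density sampling. For each case, in
ascending index-date order, `match_ratio` controls are drawn uniformly
(seeded) from the risk set: same sex, birth-year difference ≤
`age_match_tolerance_years` (default 0 — near-exact age matching), study
entry on or before the index date, under observation and alive on it, no AF
code on or before it, and not previously used as a control. Requiring the
candidate's *study entry* (not merely registration start) to precede the
index date keeps the risk set symmetric with the case definition: a control
is someone who would have been counted as a case had they converted that
day. Patients who later develop AF are eligible controls before their own
onset; no control is reused. Cases with an empty risk set are dropped with a
log message, and a warning fires if more than 1% drop. Matching is 1:1 by
default ("an equal number of controls"); `match_ratio` generalises it.

### Windows

`window_years` (default 5) converts to whole days as round(365.25 × W), so
fractional windows are well-defined and the same window length applies to
every index date regardless of leap-day placement. Windows are half-open and
exclude the index day itself: diagnostic-day contacts are mechanically
coupled to the diagnosis and would contaminate both periods. The AF
phenotype codes are excluded from scanned conditions for the same
definitional reason. Codes carried by fewer than `min_case_patients`
(default 5, mirroring small-cell disclosure conventions for UK EHR outputs)
cases in a stratum are dropped.

### Frequency ratio and ties

FR = n_case / n_control (the pair denominators cancel). When n_control = 0
the continuity correction c (default 0.5) is added to both counts, giving
(n_case + c)/c, and the result is flagged (`zero_control_flag`) so readers
can distinguish unstable ratios. n_case = 0 is undefined by construction
(such codes are filtered first). Ranking uses the deterministic total order
(descending FR, descending pct_case, ascending code string), so equal ratios
cannot reorder across runs or input permutations.

### Balanced bootstrap

The resampling unit is the matched pair, preserving the matched design. A
plan concatenates B copies of {1..n_pairs}, applies one seeded permutation,
and cuts B consecutive blocks: each pair then appears exactly B times overall
(balance holds by construction), which removes between-replicate sampling
imbalance relative to the ordinary bootstrap. Each replicate recomputes both
counts with pair multiplicities as weights; a replicate with a zero count in
either arm uses the same symmetric continuity rule as the point estimate.
Intervals are percentile intervals whose endpoints are exact order statistics
(indices ⌊α/2·B⌋ and ⌈(1−α/2)·B⌉−1 of the sorted replicates); BCa or
studentised flavours were deliberately not implemented — percentile intervals
are the simplest method consistent with reporting "bootstrap distributions",
and a plan object is exposed for anyone wanting alternatives. CIs are
computed for the ranked leading set to bound compute; passing a larger code
map to `bootstrap_cis` lifts that restriction.

### Disease groups

Fourteen groups cover the clinical taxonomy: cardiac-related (with
subcategories arrhythmia, heart failure, valve disease, cardiomyopathy,
ischaemic, other), cerebrovascular, peripheral/other vascular,
bleeding/haemorrhagic, infection, cancer, respiratory,
endocrine/nutritional/metabolic, gastrointestinal, renal, haematological,
osteoarticular & muscular, frailty/multimorbidity, and other. ICD-10 codes
classify by ordered rules — exact per-code overrides first, then the longest
matching three-character block prefix (e.g. C00–D48 → cancer, I63–I69 →
cerebrovascular, I60–I62 → bleeding), defaulting to "other". The overrides
pin down clinically-motivated placements that cut across chapters
(haemorrhages under bleeding wherever coded; endocarditis, pneumonia and
other infective diagnoses under infection; lymphoedema under vascular).
One reference entry is irreducibly ambiguous: I31.9 appears under two
different groups in the packaged pre- and post-index hospital lists; the
scheme follows the pre-index placement and the discrepancy is enumerated in
`fixture_exceptions.csv` rather than silently "corrected". Primary-care
reference entries are free-text Read terms without codes and classify
through an explicit normalised-term table that reproduces the packaged lists
exactly.

### Iris plot

Four polar panels (hospital/GP × pre/post). Each ranked condition is a bar of
length FR on a per-panel linear radial scale (different panels legitimately
need different scales; a log option exists for heavy-tailed ratios). Sectors
follow a fixed clock-face group order starting with bleeding at 12 o'clock
and proceeding clockwise; the caption convention gives only clock hours, so
within that order each sector's width is proportional to its bar count and
bars sort by descending FR within their sector. Rendering pins the SVG hash
salt and strips timestamps so identical inputs give byte-identical SVG.

## Synthetic-EHR generator

The generator emulates the study *conditions*, not the source database:

* registry rows with Bernoulli sex, uniform birth years, and registration
  intervals overlapping the study period (placement can be pinned via
  `registration_start_years` when calibration studies need untruncated
  windows);
* AF onsets as the first event of a constant-hazard process over each
  patient's registered, in-study adult time — onsets outside observation are
  non-cases, and each case emits one hospital AF code at onset;
* per-(patient, code) homogeneous Poisson event streams, independent across
  codes and patients, confined to registration; for cases the rate of a
  planted code is multiplied by `pre_ratio` on [onset−W, onset) and
  `post_ratio` on (onset, onset+W].

Because planted effects are *rate* multipliers while the scan estimates
*patient-level occurrence* ratios, the implied estimand is computed
analytically — (1−e^{−r·λ·W})/(1−e^{−λ·W}) — and exposed via
`GroundTruth.implied_ratio` for recovery tests.

Deliberately absent, and therefore untested by passing checks: correlated
multimorbidity between codes, mortality (and hence the competing-risk
censoring that depresses post-index counts in real AF cohorts, a limitation
the underlying design shares), care-seeking heterogeneity, secular coding
trends, and calibration to real incidence or code prevalences. Results on
synthetic data validate the *machinery and its statistics*, not clinical
conclusions.

## Validation studies (frozen in `ehrwas.scenarios`)

* **Ranking contract** — 8,000 patients, 160 codes per care setting with
  log-uniform base rates 0.03–0.2/patient-year, AF hazard 0.012/year: every
  stratum has ≥ 150 qualifying codes and reports exactly the leading 100.
* **Null calibration** — 100 hospital codes (rates 0.05–0.3/year), all
  planted ratios 1, 500 pairs, B = 2,000, registration 1980–1990 starts with
  30–45-year spans so five-year windows are essentially never truncated:
  the fraction of 95% CIs excluding 1 must fall in [0.01, 0.12] and a sign
  test of the log-ratios must not reject centring at 0 (p > 0.01).
* **Recovery** — one code at 0.08/year with pre-window rate ratio 4
  (implied patient-level FR ≈ 2.42), AF hazard 0.005/year, 500 pairs,
  50 seeded replications: the 95% CI must cover the implied value in ≥ 90%
  of runs. The low hazard bounds the contamination bias from controls that
  convert to AF shortly after the index date (their own pre-onset boost can
  overlap the pair's window), keeping it well inside CI width.
* **Oracle equivalence** — windowing, counting, matching and bootstrap CIs
  reproduce naive brute-force recomputations exactly on toy fixtures.

Scenario sizes are the package's choice of desk-scale study conditions; the
suite completes in about a minute on one CPU.

## Numerical and degenerate-input conventions

* All randomness flows from integer seeds through `numpy` Generators with
  per-stage streams; regeneration is bit-identical and output is invariant
  to the storage order of input rows (events are canonically sorted on all
  columns).
* Dates are whole calendar days (ISO-8601 in files); no times.
* ICD-10 codes normalise to dotted form on read (`I635` → `I63.5`); Read
  codes are stored verbatim, dots included.
* Compound printed codes ("I50.0/I50.1") classify by their first token.
* Zero eligible patients, zero cases, or empty risk sets everywhere yield an
  explicit `PipelineError`, never silently empty output; an unwritable
  output path raises the underlying I/O error.
* A degenerate bootstrap (code carried by every member of every pair)
  collapses to the point interval [1, 1], as it should.
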