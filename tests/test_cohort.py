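import datetime as dt

import numpy as np
import pandas as pd
import pytest

from ehrwas import cohort
from ehrwas.types import StudyConfig

from conftest import event, events_frame, patient, patients_frame


@pytest.fixture
def config():
    return StudyConfig(rng_seed=42)


class TestEligibility:
    # boundary patients with hand-evaluated eligibility under the default
    # rules: adult (>=18) at study entry, >=1 year registered, registration
    # overlapping 1998-01-01..2016-05-31, no AF before entry
    CASES = [
        # (patient kwargs, AF event date or None, eligible?)
        (dict(pid="child", birth=2005, start="2008-01-01", end="2015-01-01"),
         None, False),                      # aged 5 at entry
        (dict(pid="adult", birth=1950, start="1995-01-01", end="2010-01-01"),
         None, True),                       # plain eligible adult
        (dict(pid="early", birth=1950, start="1990-01-01", end="1997-06-30"),
         None, False),                      # deregistered before study start
        (dict(pid="late", birth=1950, start="2016-01-01", end="2018-01-01"),
         None, False),                      # <1y registered within study
        (dict(pid="priorAF", birth=1950, start="1995-01-01", end="2010-01-01"),
         "1997-05-01", False),              # AF before 1998 entry
        (dict(pid="laterAF", birth=1950, start="1995-01-01", end="2010-01-01"),
         "1999-06-01", True),               # AF after entry: still in cohort
        (dict(pid="deadpre", birth=1950, start="1995-01-01", end="2005-01-01",
              death="1997-12-31"), None, False),  # died before study start
        (dict(pid="just18", birth=1980, start="1995-01-01", end="2010-01-01"),
         None, True),                       # turns 18 in the entry year
        (dict(pid="just17", birth=1981, start="1995-01-01", end="2010-01-01"),
         None, False),                      # 17 at entry
        (dict(pid="shortreg", birth=1950, start="1997-01-01",
              end="1998-01-10"), None, True),   # 1y done just inside study
        (dict(pid="newreg", birth=1950, start="2010-01-01", end="2014-01-01"),
         None, True),                       # entry 2011-01-01, inside study
    ]

    def test_membership_matches_hand_evaluated_truth_table(self, config):
        pats, evts, expected = [], [], set()
        for kwargs, af_date, ok in self.CASES:
            pid = kwargs.pop("pid")
            pats.append(patient(pid, **kwargs))
            if af_date:
                evts.append(event(pid, af_date, "I48.1"))
            if ok:
                expected.add(pid)
        frame = patients_frame(*pats)
        events = events_frame(*evts) if evts else events_frame(
            event("nobody", "2000-01-01", "J18.9"))
        from ehrwas.phenotypes import load_af_codes
        eligible = cohort.apply_eligibility(frame, events, load_af_codes(),
                                            config)
        assert set(eligible["patient_id"]) == expected

    def test_entry_date_is_later_of_study_start_and_one_year_registered(
            self, config, af_codes):
        frame = patients_frame(
            patient("a", start="1995-01-01", end="2010-01-01"),
            patient("b", start="2010-01-01", end="2014-01-01"),
        )
        events = events_frame(event("x", "2000-01-01", "J18.9"))
        eligible = cohort.apply_eligibility(frame, events, af_codes, config)
        entry = dict(zip(eligible["patient_id"], eligible["entry_date"]))
        assert entry["a"] == pd.Timestamp("1998-01-01")
        assert entry["b"] == pd.Timestamp("2011-01-01")


class TestIdentifyCases:
    def run(self, config, af_codes, *evts,
            start="1995-01-01", end="2012-01-01"):
        frame = patients_frame(patient("p", start=start, end=end))
        events = events_frame(*evts)
        eligible = cohort.apply_eligibility(frame, events, af_codes, config)
        return cohort.identify_cases(eligible, events, af_codes, config)

    def test_index_is_earliest_qualifying_af_code(self, config, af_codes):
        cases = self.run(config, af_codes,
                         event("p", "2004-03-01", "I48.1"),
                         event("p", "2006-01-01", "G573.00", setting="primary"))
        assert list(cases["index_date"]) == [pd.Timestamp("2004-03-01")]

    def test_icd_matching_is_prefix_based_and_excludes_i47(self, config,
                                                           af_codes):
        cases = self.run(config, af_codes, event("p", "2004-03-01", "I47.1"))
        assert cases.empty

    def test_af_code_after_registration_end_is_not_a_case(self, config,
                                                          af_codes):
        cases = self.run(config, af_codes, event("p", "2013-01-01", "I48.1"),
                         end="2012-01-01")
        assert cases.empty

    def test_read_matching_is_exact_not_prefix(self, config, af_codes):
        cases = self.run(config, af_codes,
                         event("p", "2004-03-01", "G573411", setting="primary"))
        assert cases.empty


class TestMatching:
    def test_single_compatible_candidate_is_matched(self, config, af_codes):
        frame = patients_frame(
            patient("case", sex="F", birth=1940, start="1995-01-01",
                    end="2010-01-01"),
            patient("ctrl", sex="F", birth=1940, start="2000-01-01",
                    end="2010-01-01"),
        )
        events = events_frame(event("case", "2005-06-01", "I48.1"))
        eligible = cohort.apply_eligibility(frame, events, af_codes, config)
        cases = cohort.identify_cases(eligible, events, af_codes, config)
        pairs = cohort.match_controls(cases, eligible, events, af_codes, config)
        assert list(pairs["control_id"]) == ["ctrl"]
        assert list(pairs["index_date"]) == [pd.Timestamp("2005-06-01")]

    def test_candidate_with_prior_af_is_excluded_from_risk_set(self, config,
                                                               af_codes):
        frame = patients_frame(
            patient("case", start="1995-01-01", end="2010-01-01"),
            patient("ctrl", start="1999-01-01", end="2010-01-01"),
        )
        # candidate's AF (2003) predates the case's index (2005): not at risk;
        # note the candidate survives eligibility (AF after their 2000 entry)
        events = events_frame(event("case", "2005-06-01", "I48.1"),
                              event("ctrl", "2003-01-01", "I48.1"))
        eligible = cohort.apply_eligibility(frame, events, af_codes, config)
        assert "ctrl" in set(eligible["patient_id"])
        cases = cohort.identify_cases(eligible, events, af_codes, config)
        pairs = cohort.match_controls(
            cases.loc[cases["patient_id"] == "case"], eligible, events,
            af_codes, config)
        assert pairs.empty

    def test_future_case_can_serve_as_control_before_its_onset(self, config,
                                                               af_codes):
        frame = patients_frame(
            patient("case", start="1995-01-01", end="2010-01-01"),
            patient("later", start="1995-01-01", end="2012-01-01"),
        )
        events = events_frame(event("case", "2005-06-01", "I48.1"),
                              event("later", "2008-01-01", "I48.1"))
        eligible = cohort.apply_eligibility(frame, events, af_codes, config)
        cases = cohort.identify_cases(eligible, events, af_codes, config)
        pairs = cohort.match_controls(cases, eligible, events, af_codes, config)
        matched = dict(zip(pairs["case_id"], pairs["control_id"]))
        assert matched.get("case") == "later"
        # but "later"'s own case (index 2008) now has no remaining candidate
        assert "later" not in matched

    def test_matches_equal_brute_force_reimplementation(self, config, af_codes):
        # 5 cases, 20 candidates, same seed: the pair set must equal an
        # independent re-implementation that walks cases in index order and
        # consumes the same seeded random stream
        rng_pop = np.random.default_rng(99)
        pats = [patient(f"case{i}", sex="F", birth=1940,
                        start="1995-01-01", end="2012-01-01")
                for i in range(5)]
        pats += [patient(f"cand{i:02d}", sex="F",
                         birth=1940 + int(rng_pop.integers(0, 2)),
                         start="1995-01-01", end="2012-01-01")
                 for i in range(20)]
        frame = patients_frame(*pats)
        evts = [event(f"case{i}", f"200{i + 1}-03-01", "I48.1")
                for i in range(5)]
        events = events_frame(*evts)
        eligible = cohort.apply_eligibility(frame, events, af_codes, config)
        cases = cohort.identify_cases(eligible, events, af_codes, config)
        pairs = cohort.match_controls(cases, eligible, events, af_codes, config)

        # --- brute force oracle ---
        pool = sorted(
            (r for r in frame.itertuples(index=False)),
            key=lambda r: r.patient_id)
        rng = np.random.default_rng([config.rng_seed % (2**31), 11])
        used = set()
        expected = {}
        af_dates = {f"case{i}": pd.Timestamp(f"200{i + 1}-03-01")
                    for i in range(5)}
        for case in cases.sort_values(["index_date", "patient_id"]).itertuples(
                index=False):
            t = case.index_date
            case_birth = 1940
            cand_positions = []
            for pos, rec in enumerate(pool):
                pid = rec.patient_id
                if pid == case.patient_id or pid in used:
                    continue
                if rec.sex != "F" or abs(rec.birth_year - case_birth) > 0:
                    continue
                entry = max(rec.reg_start + pd.Timedelta(days=365),
                            pd.Timestamp("1998-01-01"))
                if not (entry <= t <= min(rec.reg_end,
                                          pd.Timestamp("2016-05-31"))):
                    continue
                if pid in af_dates and af_dates[pid] <= t:
                    continue
                cand_positions.append(pos)
            chosen = rng.choice(np.array(cand_positions), size=1,
                                replace=False)
            pid = pool[int(chosen[0])].patient_id
            used.add(pid)
            expected[case.patient_id] = pid

        assert dict(zip(pairs["case_id"], pairs["control_id"])) == expected

    def test_pair_invariants_hold_on_synthetic_run(self, af_codes):
        from ehrwas import scenarios
        study = StudyConfig(rng_seed=5)
        cfg = scenarios.null_scenario(5, n_codes=5)
        cfg.n_patients = 800
        patients_df, events, pairs = scenarios.matched_pairs(cfg, study)
        assert len(pairs) > 50
        # no control reused, case != control, sexes equal, birth years equal
        assert pairs["control_id"].is_unique
        assert (pairs["case_id"] != pairs["control_id"]).all()
        assert (pairs["age_difference_years"].abs()
                <= study.age_match_tolerance_years).all()
        merged = pairs.merge(patients_df, left_on="control_id",
                             right_on="patient_id")
        assert (merged["sex_x"] == merged["sex_y"]).all()
        assert (merged["reg_start"] <= merged["index_date"]).all()
        assert (merged["reg_end"] >= merged["index_date"]).all()

    def test_output_invariant_to_input_row_order(self, config, af_codes):
        rng = np.random.default_rng(1)
        pats = [patient(f"p{i:02d}", birth=1940,
                        start="1995-01-01", end="2012-01-01")
                for i in range(30)]
        frame = patients_frame(*pats)
        evts = [event(f"p{i:02d}", "2005-03-01", "I48.1") for i in range(4)]
        events = events_frame(*evts)
        eligible = cohort.apply_eligibility(frame, events, af_codes, config)
        cases = cohort.identify_cases(eligible, events, af_codes, config)
        pairs1 = cohort.match_controls(cases, eligible, events, af_codes,
                                       config)
        shuffled = eligible.sample(frac=1.0, random_state=4).reset_index(
            drop=True)
        pairs2 = cohort.match_controls(cases, shuffled, events, af_codes,
                                       config)
        pd.testing.assert_frame_equal(pairs1, pairs2)
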