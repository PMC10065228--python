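"""Cohort construction: case identification with back-dating, eligibility
boundaries, 1:ratio matching constraints, and the train/test split."""

import numpy as np
import pandas as pd
import pytest

from aspredict import cohort, synth
from aspredict.codes import male_signature
from conftest import make_events, make_patients


# ---------------------------------------------------------------------------
# case identification
# ---------------------------------------------------------------------------

class TestIdentifyCases:
    def test_earliest_as_code_across_sources_wins(self):
        events = make_events([
            ("p1", "M4500", "HOSP", "diagnosis", "2010-06-01"),
            ("p1", "N1000", "GP", "diagnosis", "2011-01-01"),
            ("p2", "sAS00", "RHEUM", "diagnosis", "2005-03-03"),
            ("p3", "24601", "GP", "diagnosis", "2008-01-01"),  # no AS code
        ])
        found = cohort.identify_cases(events)
        assert list(found["patient_id"]) == ["p1", "p2"]
        assert found.loc[0, "diagnosis_date"] == pd.Timestamp("2010-06-01")
        assert found["suspected_date"].isna().all()

    def test_anti_tnf_before_first_as_code_backdates(self):
        events = make_events([
            ("p1", "dTNF1", "GP", "prescription", "2009-09-01"),
            ("p1", "N1000", "GP", "diagnosis", "2010-06-01"),
        ])
        found = cohort.identify_cases(events)
        assert found.loc[0, "suspected_date"] == pd.Timestamp("2009-09-01")

    def test_hla_b27_or_spa_code_before_first_as_code_backdates(self):
        events = make_events([
            ("p1", "43HB7", "GP", "test", "2009-02-01"),
            ("p1", "N1010", "GP", "diagnosis", "2009-08-01"),
            ("p1", "N1000", "GP", "diagnosis", "2010-06-01"),
        ])
        found = cohort.identify_cases(events)
        assert found.loc[0, "suspected_date"] == pd.Timestamp("2009-02-01")

    def test_qualifying_codes_after_first_as_code_do_not_backdate(self):
        events = make_events([
            ("p1", "N1000", "GP", "diagnosis", "2010-06-01"),
            ("p1", "dTNF1", "GP", "prescription", "2011-01-01"),
        ])
        found = cohort.identify_cases(events)
        assert pd.isna(found.loc[0, "suspected_date"])

    def test_agrees_with_brute_force_oracle(self, small_male_population):
        _, patients, events = small_male_population
        ev = synth.inject_suspected_pathway(patients, events, 0.4, seed=9)
        found = cohort.identify_cases(ev).set_index("patient_id")
        cl = cohort.CodeLists()
        as_pref = tuple(sorted(cl.as_prefixes))
        sus_pref = tuple(sorted(cl.anti_tnf_prefixes | cl.hla_b27_prefixes
                                | cl.spa_prefixes))
        oracle = {}
        for pid, grp in ev.groupby("patient_id"):
            as_dates = [d for c, d in zip(grp["code"], grp["event_date"])
                        if c.startswith(as_pref)]
            if not as_dates:
                continue
            diag = min(as_dates)
            sus = [d for c, d in zip(grp["code"], grp["event_date"])
                   if c.startswith(sus_pref) and d < diag]
            oracle[pid] = (diag, min(sus) if sus else pd.NaT)
        assert set(found.index) == set(oracle)
        for pid, (diag, sus) in oracle.items():
            assert found.loc[pid, "diagnosis_date"] == diag
            got = found.loc[pid, "suspected_date"]
            assert (pd.isna(got) and pd.isna(sus)) or got == sus


# ---------------------------------------------------------------------------
# eligibility
# ---------------------------------------------------------------------------

def _one_case(diag, wob="1990-01-01", reg_start="2000-01-03",
              reg_end="2030-01-01"):
    cases = pd.DataFrame({"patient_id": ["p1"],
                          "diagnosis_date": [pd.Timestamp(diag)],
                          "suspected_date": [pd.NaT]})
    patients = make_patients([
        ("p1", "male", wob, reg_start, reg_end, "case", diag)])
    return cases, patients


def _eligible_case(diag, patients, **kwargs):
    """Cases frame carrying demographics, as apply_eligibility produces."""
    cases, _ = _one_case(diag, **kwargs)
    return cases.merge(patients[["patient_id", "sex", "week_of_birth",
                                 "reg_start", "reg_end"]], on="patient_id")


class TestEligibility:
    def test_age_below_fifteen_excluded(self):
        cases, patients = _one_case("2004-06-01")  # age ~14.4
        kept, attr = cohort.apply_eligibility(cases, patients, cohort.MatchConfig())
        assert kept.empty
        assert attr.set_index("filter").loc["age_at_diagnosis", "n_removed"] == 1

    def test_age_thirty_five_inclusive(self):
        cases, patients = _one_case("2025-01-01")  # age ~35.0 (wob 1990-01-01)
        kept, _ = cohort.apply_eligibility(cases, patients, cohort.MatchConfig())
        assert len(kept) == 1

    def test_diagnosis_before_2000_excluded(self):
        cases, patients = _one_case("1999-12-31", wob="1982-01-04",
                                    reg_start="1995-01-02")
        kept, attr = cohort.apply_eligibility(cases, patients, cohort.MatchConfig())
        assert kept.empty
        assert attr.set_index("filter").loc["diagnosis_year", "n_removed"] == 1

    def test_exactly_three_years_prior_registration_retained(self):
        cases, patients = _one_case("2010-06-01", reg_start="2007-06-01")
        kept, _ = cohort.apply_eligibility(cases, patients, cohort.MatchConfig())
        assert len(kept) == 1
        cases, patients = _one_case("2010-06-01", reg_start="2007-06-02")
        kept, attr = cohort.apply_eligibility(cases, patients, cohort.MatchConfig())
        assert kept.empty
        assert attr.set_index("filter").loc["prior_registration", "n_removed"] == 1

    def test_attrition_recount_matches_brute_force(self, small_male_population):
        _, patients, events = small_male_population
        found = cohort.identify_cases(events)
        cfg = cohort.MatchConfig()
        kept, attr = cohort.apply_eligibility(found, patients, cfg)
        # independent recount: apply all filters at once
        m = found.merge(patients[["patient_id", "week_of_birth", "reg_start"]],
                        on="patient_id")
        age = cohort.age_at(m["diagnosis_date"], m["week_of_birth"])
        ok = ((age >= 15) & (age <= 35)
              & (m["diagnosis_date"].dt.year >= 2000)
              & (m["reg_start"] <= m["diagnosis_date"]
                 - pd.offsets.DateOffset(years=3)))
        assert len(kept) == int(ok.sum())
        assert attr.loc[attr["filter"] == "retained", "n_removed"].iloc[0] == len(kept)


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def matched_small():
    cfg = synth.SynthConfig(n_cases=20, controls_per_case=10, sex_ratio=1.0,
                            seed=21)
    patients, events = synth.generate_population(cfg, [male_signature()])
    found = cohort.identify_cases(events)
    mcfg = cohort.MatchConfig(ratio=10, seed=4)
    eligible, _ = cohort.apply_eligibility(found, patients, mcfg)
    matched = cohort.match_controls(eligible, patients, events, mcfg)
    return patients, events, eligible, mcfg, matched


class TestMatching:
    def test_every_pair_satisfies_the_matching_constraints(self, matched_small):
        patients, _, eligible, mcfg, matched = matched_small
        t = matched.table
        demo = patients.set_index("patient_id")
        diag = eligible.set_index("patient_id")["diagnosis_date"]
        tol = pd.Timedelta(weeks=mcfg.birth_tolerance_weeks)
        ctl = t[t["role"] == "control"]
        assert len(ctl) == len(eligible) * mcfg.ratio
        for row in ctl.itertuples(index=False):
            c, k = demo.loc[row.patient_id], demo.loc[row.matched_case_id]
            assert c["sex"] == k["sex"]
            assert abs(c["week_of_birth"] - k["week_of_birth"]) <= tol
            assert row.index_date == diag.loc[row.matched_case_id]  # calendar mode
            assert c["reg_start"] + pd.offsets.DateOffset(years=3) <= row.index_date
            assert row.index_date + pd.offsets.DateOffset(years=3) <= c["reg_end"]
            assert c["true_status"] == "control"

    def test_no_control_repeated_within_a_case(self, matched_small):
        *_, matched = matched_small
        ctl = matched.table[matched.table["role"] == "control"]
        per_case = ctl.groupby("matched_case_id")["patient_id"].nunique()
        assert (per_case == matched.ratio).all()

    def test_unit_ids_are_unique(self, matched_small):
        *_, matched = matched_small
        assert matched.table["unit_id"].is_unique

    def test_short_registration_controls_never_selected(self):
        """A control with under six years of registration can never host a
        three-year window on both sides of an index date."""
        _, patients = _one_case("2010-06-01", reg_start="2005-01-03")
        short = make_patients([
            ("c1", "male", "1990-01-01", "2008-01-07", "2013-01-07",
             "control", pd.NaT)])
        pool = pd.concat([patients, short], ignore_index=True)
        cases = _eligible_case("2010-06-01", pool, reg_start="2005-01-03")
        events = make_events([("p1", "N1000", "GP", "diagnosis", "2010-06-01")])
        with pytest.raises(cohort.MatchingError, match="index feasibility: 0"):
            cohort.match_controls(cases, pool, events, cohort.MatchConfig(ratio=1))

    def test_zero_birth_tolerance_requires_identical_week(self):
        _, patients = _one_case("2010-06-01", wob="1990-01-01")
        near = make_patients([
            ("c1", "male", "1990-01-08", "2000-01-03", "2030-01-01",
             "control", pd.NaT)])  # one week off
        pool = pd.concat([patients, near], ignore_index=True)
        cases = _eligible_case("2010-06-01", pool)
        events = make_events([("p1", "N1000", "GP", "diagnosis", "2010-06-01")])
        with pytest.raises(cohort.MatchingError):
            cohort.match_controls(cases, pool, events,
                                  cohort.MatchConfig(ratio=1,
                                                     birth_tolerance_weeks=0))

    def test_as_code_carriers_excluded_from_the_pool(self):
        _, patients = _one_case("2010-06-01")
        carrier = make_patients([
            ("c1", "male", "1990-01-01", "2000-01-03", "2030-01-01",
             "control", pd.NaT)])
        pool = pd.concat([patients, carrier], ignore_index=True)
        cases = _eligible_case("2010-06-01", pool)
        events = make_events([
            ("p1", "N1000", "GP", "diagnosis", "2010-06-01"),
            ("c1", "M4600", "HOSP", "diagnosis", "2015-01-01"),  # axial SpA
        ])
        with pytest.raises(cohort.MatchingError):
            cohort.match_controls(cases, pool, events, cohort.MatchConfig(ratio=1))

    def test_matching_is_deterministic(self, matched_small):
        patients, events, eligible, mcfg, matched = matched_small
        again = cohort.match_controls(eligible, patients, events, mcfg)
        pd.testing.assert_frame_equal(matched.table, again.table)


# ---------------------------------------------------------------------------
# split
# ---------------------------------------------------------------------------

def _toy_cohort(n_cases, ratio=2):
    rows = []
    for i in range(n_cases):
        cid = f"p{i:03d}"
        rows.append((cid, cid, "case", pd.NA, cid, pd.Timestamp("2010-01-01")))
        for k in range(ratio):
            rows.append((f"{cid}c{k}", f"{cid}c{k}", "control", k + 1, cid,
                         pd.Timestamp("2010-01-01")))
    table = pd.DataFrame(rows, columns=["unit_id", "patient_id", "role",
                                        "control_set", "matched_case_id",
                                        "index_date"])
    table["control_set"] = table["control_set"].astype("Int64")
    table["split"] = pd.NA
    return cohort.MatchedCohort(table=table, ratio=ratio)


class TestSplit:
    @pytest.mark.parametrize("n,expect_train", [(543, 380), (250, 175)])
    def test_seventy_thirty_counts(self, n, expect_train):
        out = cohort.split_train_test(_toy_cohort(n), train_fraction=0.7, seed=1)
        t = out.table
        n_train = (t.loc[t["role"] == "case", "split"] == "train").sum()
        assert n_train == expect_train

    def test_controls_inherit_their_case_split(self):
        out = cohort.split_train_test(_toy_cohort(30), seed=2)
        t = out.table
        case_split = t[t["role"] == "case"].set_index("patient_id")["split"]
        ctl = t[t["role"] == "control"]
        assert (ctl["split"].to_numpy()
                == case_split.loc[ctl["matched_case_id"]].to_numpy()).all()

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(ValueError):
            cohort.split_train_test(_toy_cohort(10), train_fraction=1.0)


def test_cohort_round_trip(tmp_path, matched_small):
    *_, matched = matched_small
    out = cohort.split_train_test(matched, seed=0)
    path = tmp_path / "cohort.csv"
    cohort.write_cohort(out, path)
    back = cohort.read_cohort(path, ratio=out.ratio)
    pd.testing.assert_frame_equal(
        out.table.reset_index(drop=True), back.table, check_dtype=False)
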