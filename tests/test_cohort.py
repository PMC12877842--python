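"""Patient-selection logic: loss events, criteria, exclusions, subgroups."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rplphewas import cohort as cm
from rplphewas import synth
from rplphewas.ehr_io import EhrBundle

BASE = pd.Timestamp("2015-01-01")
DAY = pd.Timedelta(days=1)


def days(*offsets):
    return [BASE + int(o) * DAY for o in offsets]


class TestDistinctLossEvents:
    @pytest.mark.parametrize(
        "offsets, expected",
        [
            ([0, 89], [0]),
            ([0, 90], [0, 90]),
            ([0, 91], [0, 91]),
            ([0, 50, 95, 200], [0, 95, 200]),
            ([0], [0]),
            ([], []),
            ([0, 90, 170], [0, 90]),  # 170 is only 80 days after event start 90
        ],
    )
    def test_greedy_scan(self, offsets, expected):
        assert cm.distinct_loss_events(days(*offsets)) == days(*expected)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            cm.distinct_loss_events(days(10, 0))

    @given(
        offsets=st.lists(st.integers(0, 2000), min_size=0, max_size=15),
        gap_small=st.integers(0, 90),
        gap_big=st.integers(91, 200),
    )
    @settings(max_examples=100, deadline=None)
    def test_lowering_gap_never_decreases_events(self, offsets, gap_small, gap_big):
        dates = days(*sorted(offsets))
        n_small = len(cm.distinct_loss_events(dates, gap_small))
        n_big = len(cm.distinct_loss_events(dates, gap_big))
        assert n_small >= n_big
        events = cm.distinct_loss_events(dates, gap_big)
        assert set(events) <= set(dates)
        if dates:
            assert events[0] == dates[0]


def mini_bundle(conditions, persons=None, gender="female"):
    pids = sorted({c[0] for c in conditions})
    persons = persons or [
        {"person_id": pid, "birth_date": pd.Timestamp("1985-06-15"),
         "gender": gender, "race": "White", "ethnicity": "Unknown"}
        for pid in pids
    ]
    return EhrBundle(
        "mini",
        pd.DataFrame(persons),
        pd.DataFrame(
            [{"person_id": p, "concept_id": c, "start_date": BASE + d * DAY}
             for p, c, d in conditions]
        ),
        pd.DataFrame({"person_id": pd.Series(dtype=str),
                      "visit_date": pd.Series(dtype="datetime64[ns]")}),
    )


LOSS = synth.LOSS_CONCEPTS[0]
BIRTH = synth.BIRTH_CONCEPTS[0]
CS = synth.default_concept_sets()


class TestSelectRpl:
    def test_history_then_loss_qualifies_at_loss_date(self):
        b = mini_bundle([("A", synth.HISTORY_CONCEPT, 100), ("A", LOSS, 300)])
        out = cm.select_rpl(b, CS)
        assert list(out["person_id"]) == ["A"]
        assert out.loc[0, "index_date"] == BASE + 300 * DAY
        assert out.loc[0, "n_distinct_losses"] == 1

    def test_single_loss_not_selected(self):
        b = mini_bundle([("A", LOSS, 0)])
        assert cm.select_rpl(b, CS).empty

    def test_index_is_minimum_over_criteria(self):
        b = mini_bundle([("A", LOSS, 0), ("A", LOSS, 90),
                         ("A", synth.RPL_DX_CONCEPT, 50)])
        out = cm.select_rpl(b, CS)
        assert out.loc[0, "index_date"] == BASE + 50 * DAY

    def test_same_day_history_and_loss_does_not_qualify(self):
        b = mini_bundle([("A", synth.HISTORY_CONCEPT, 100), ("A", LOSS, 100)])
        assert cm.select_rpl(b, CS).empty


class TestSelectControls:
    def test_live_birth_without_exclusions(self):
        b = mini_bundle([("A", BIRTH, 500)])
        out = cm.select_controls(b, CS)
        assert out.loc[0, "index_date"] == BASE + 500 * DAY

    def test_any_history_exclusion_removes(self):
        b = mini_bundle([("A", BIRTH, 500), ("A", "EX_PRETERM_BIRTH", 900)])
        assert cm.select_controls(b, CS).empty

    def test_earliest_birth_is_index(self):
        b = mini_bundle([("A", BIRTH, 800), ("A", BIRTH, 400)])
        out = cm.select_controls(b, CS)
        assert out.loc[0, "index_date"] == BASE + 400 * DAY


class TestApplyExclusions:
    def test_age_uses_365_25_day_years(self):
        b = mini_bundle(
            [("A", LOSS, 0), ("A", LOSS, 90), ("A", "J06.9", 10)],
            persons=[{"person_id": "A", "birth_date": pd.Timestamp("1988-01-01"),
                      "gender": "female", "race": "W", "ethnicity": "U"}],
        )
        members = pd.DataFrame(
            {"person_id": ["A"], "group": ["rpl"],
             "index_date": [pd.Timestamp("2023-01-01")], "n_distinct_losses": [2]}
        )
        out, report = cm.apply_exclusions(members, b, CS)
        assert out.loc[0, "age_at_index"] == pytest.approx(12784 / 365.25)
        assert len(out) == 1

    def test_gender_rule(self):
        # male with no pregnancy evidence: removed; other-gender with a loss
        # record (incident-pregnancy evidence): retained
        b = mini_bundle(
            [("M", synth.RPL_DX_CONCEPT, 0), ("M", "J06.9", 5),
             ("O", LOSS, 0), ("O", LOSS, 90), ("O", "J06.9", 5)],
            persons=[
                {"person_id": "M", "birth_date": pd.Timestamp("1985-06-15"),
                 "gender": "male", "race": "W", "ethnicity": "U"},
                {"person_id": "O", "birth_date": pd.Timestamp("1985-06-15"),
                 "gender": "other", "race": "W", "ethnicity": "U"},
            ],
        )
        members = cm.select_rpl(b, CS)
        out, report = cm.apply_exclusions(members, b, CS)
        assert list(out["person_id"]) == ["O"]
        assert report.removed["gender_no_pregnancy"] == {"rpl": 1}


class TestHandcraftedFixture:
    """Record-by-record enumeration of the 25-patient bundle."""

    def test_final_membership(self, fixture_bundle):
        bundle, cs = fixture_bundle
        cohort, report = cm.build_cohort(bundle, cs)
        rpl = set(cohort.loc[cohort["group"] == "rpl", "person_id"])
        ctl = set(cohort.loc[cohort["group"] == "control", "person_id"])
        assert rpl == {"P02", "P03", "P04", "P05", "P07", "P20", "P23", "P25"}
        assert ctl == {"P09", "P10", "P15", "P21", "P24"}

    def test_index_dates(self, fixture_bundle):
        bundle, cs = fixture_bundle
        cohort, _ = cm.build_cohort(bundle, cs)
        idx = cohort.set_index("person_id")["index_date"]
        expected = {"P02": 90, "P03": 91, "P04": 95, "P05": 300, "P07": 50,
                    "P20": 90, "P23": 90, "P25": 90, "P09": 500, "P10": 400,
                    "P15": 500, "P21": 500, "P24": 200}
        for pid, off in expected.items():
            assert idx[pid] == BASE + off * DAY, pid

    def test_exclusion_report_arms(self, fixture_bundle):
        bundle, cs = fixture_bundle
        _, report = cm.build_cohort(bundle, cs)
        assert report.initial == {"rpl": 13, "control": 6}
        assert report.removed["age_out_of_range"] == {"rpl": 2}
        assert report.removed["gender_no_pregnancy"] == {"rpl": 1}
        assert report.removed["record_span_100y"] == {"rpl": 1}
        assert report.removed["no_diagnoses"] == {"rpl": 1, "control": 1}
        assert report.final == {"rpl": 8, "control": 5}
        for group in ("rpl", "control"):
            removed = sum(arm.get(group, 0) for arm in report.removed.values())
            assert report.initial.get(group, 0) - removed == report.final.get(group, 0)

    def test_severe_subgroup(self, fixture_bundle):
        bundle, cs = fixture_bundle
        severe, _ = cm.select_severe_rpl(bundle, cs)
        rpl = severe[severe["group"] == "rpl"]
        assert list(rpl["person_id"]) == ["P04"]
        assert rpl.iloc[0]["index_date"] == BASE + 200 * DAY

    def test_next_outcomes(self, fixture_bundle):
        bundle, cs = fixture_bundle
        cohort, _ = cm.build_cohort(bundle, cs)
        out = cm.find_next_outcome(cohort, bundle, cs).set_index("person_id")
        assert out.loc["P04", "outcome"] == "loss"
        assert out.loc["P04", "outcome_date"] == BASE + 200 * DAY
        assert out.loc["P25", "outcome"] == "birth"
        assert out.loc["P25", "outcome_date"] == BASE + 400 * DAY
        assert "P02" not in out.index  # no outcome >= index + 30


class TestSevereRule:
    def test_three_events_index_is_third(self):
        b = mini_bundle([("A", LOSS, 0), ("A", LOSS, 90), ("A", LOSS, 180),
                         ("A", "J06.9", 10)])
        severe, _ = cm.select_severe_rpl(b, CS)
        assert severe.loc[0, "index_date"] == BASE + 180 * DAY

    def test_short_third_gap_not_severe(self):
        b = mini_bundle([("A", LOSS, 0), ("A", LOSS, 90), ("A", LOSS, 170),
                         ("A", "J06.9", 10)])
        severe, _ = cm.select_severe_rpl(b, CS)
        assert severe[severe["group"] == "rpl"].empty


class TestTenYearSubgroup:
    def test_boundaries(self):
        b = mini_bundle([
            ("A", LOSS, 0), ("A", LOSS, 90), ("A", "J06.9", -4100),
            ("B", LOSS, 0), ("B", LOSS, 90), ("B", "J06.9", -3500),
        ])
        cohort, _ = cm.build_cohort(b, CS)
        sub = cm.select_ten_year_subgroup(cohort, b)
        assert set(sub["person_id"]) == {"A"}
        assert set(sub["person_id"]) <= set(cohort["person_id"])


class TestNextOutcome:
    def test_tie_classified_loss_and_flagged(self):
        b = mini_bundle([("A", LOSS, 0), ("A", LOSS, 90), ("A", "J06.9", 10),
                         ("A", LOSS, 150), ("A", BIRTH, 150)])
        cohort, _ = cm.build_cohort(b, CS)
        out = cm.find_next_outcome(cohort, b, CS)
        assert out.loc[0, "outcome"] == "loss"
        assert bool(out.loc[0, "ambiguous"])

    def test_boundary_at_30_days(self):
        b = mini_bundle([("A", LOSS, 0), ("A", LOSS, 90), ("A", "J06.9", 10),
                         ("A", BIRTH, 119),
                         ("B", LOSS, 0), ("B", LOSS, 90), ("B", "J06.9", 10),
                         ("B", BIRTH, 120)])
        cohort, _ = cm.build_cohort(b, CS)
        out = cm.find_next_outcome(cohort, b, CS)
        assert list(out["person_id"]) == ["B"]  # 119 < index+30, 120 == index+30


def test_groups_disjoint_and_build_deterministic(small_center):
    bundle, _, _ = small_center
    cohort, _ = cm.build_cohort(bundle, synth.default_concept_sets())
    groups = cohort.groupby("person_id")["group"].nunique()
    assert (groups == 1).all()

    # shuffling condition rows does not change the cohort
    shuffled = EhrBundle(
        bundle.center_label,
        bundle.persons.sample(frac=1, random_state=3).reset_index(drop=True),
        bundle.conditions.sample(frac=1, random_state=4).reset_index(drop=True),
        bundle.visits,
    )
    cohort2, _ = cm.build_cohort(shuffled, synth.default_concept_sets())
    pd.testing.assert_frame_equal(cohort, cohort2)
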