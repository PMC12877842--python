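"""Patient selection: RPL cases, live-birth controls, exclusions, subgroups.

Selection rules
---------------
A patient joins the RPL group via any of three criteria:

(a) an explicit RPL-diagnosis record (qualifying date: that record's date);
(b) a pregnancy-loss record dated strictly after a history-of-loss record
    (qualifying date: the loss date);
(c) two or more *distinct* loss events, where loss records count as distinct
    only when a record starts at least 90 days after the start of the
    previous accepted event (qualifying date: the second event's date).

The index date is the minimum over qualifying dates. Controls require a
live-birth record and no control-exclusion record (loss, preterm
birth/labor/rupture, multiple gestation with loss, molar or extrauterine
pregnancy) anywhere in the history; their index is the earliest live birth.

Both groups then pass an ordered exclusion cascade: age outside [15, 44] at
index (365.25-day years), neither female nor any incident-pregnancy record,
a record span of 100+ years, and no ICD diagnosis inside the study window
(unbounded past through index + 365 days).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ehr_io import ConceptSet, EhrBundle

DAYS_PER_YEAR = 365.25
DEFAULT_WINDOW_DAYS = 365
TEN_YEARS_DAYS = 3652

COHORT_COLUMNS = [
    "person_id", "group", "index_date", "age_at_index", "gender", "race",
    "ethnicity", "n_visits_in_window", "ehr_years_in_window",
    "n_distinct_losses", "first_record", "last_record",
]


@dataclass
class ExclusionReport:
    """Ordered removal counts per exclusion arm, per group."""

    initial: dict = field(default_factory=dict)
    removed: dict = field(default_factory=dict)  # arm -> {group: count}
    final: dict = field(default_factory=dict)

    ARMS = ("age_out_of_range", "gender_no_pregnancy", "record_span_100y", "no_diagnoses")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"stage": "initial", **self.initial}]
        rows += [{"stage": arm, **self.removed.get(arm, {})} for arm in self.ARMS]
        rows.append({"stage": "final", **self.final})
        return pd.DataFrame(rows).fillna(0)


def distinct_loss_events(loss_dates, min_gap_days: int = 90) -> list:
    """Greedy left-to-right scan over sorted loss dates.

    The first date starts event 1; each later date starts a new event iff it
    falls at least ``min_gap_days`` after the start of the previous accepted
    event. Returns the accepted event start dates.
    """
    if min_gap_days < 0:
        raise ValueError("min_gap_days must be >= 0")
    dates = list(loss_dates)
    if any(b < a for a, b in zip(dates, dates[1:])):
        raise ValueError("loss dates must be sorted ascending")
    events = []
    for d in dates:
        if not events or (d - events[-1]) >= pd.Timedelta(days=min_gap_days):
            events.append(d)
    return events


def _conditions_in(bundle: EhrBundle, concept_ids) -> pd.DataFrame:
    return bundle.conditions[bundle.conditions["concept_id"].isin(concept_ids)]


def select_rpl(
    bundle: EhrBundle,
    concept_sets: dict[str, ConceptSet],
    min_gap_days: int = 90,
) -> pd.DataFrame:
    """Pre-exclusion RPL members: (person_id, index_date, n_distinct_losses)."""
    loss_ids = concept_sets["pregnancy_loss"].concept_ids
    losses = _conditions_in(bundle, loss_ids)
    rpl_dx = _conditions_in(bundle, concept_sets["rpl_diagnosis"].concept_ids)
    history = _conditions_in(bundle, concept_sets["history_of_loss"].concept_ids)

    qualifying: dict[str, pd.Timestamp] = {}

    # (a) explicit RPL diagnosis
    for pid, date in (
        rpl_dx.groupby("person_id")["start_date"].min().items()
    ):
        qualifying[pid] = min(qualifying.get(pid, date), date)

    loss_by_person = {pid: g["start_date"].sort_values() for pid, g in losses.groupby("person_id")}
    hist_by_person = history.groupby("person_id")["start_date"].min()

    n_distinct = {}
    for pid, dates in loss_by_person.items():
        events = distinct_loss_events(list(dates), min_gap_days)
        n_distinct[pid] = len(events)
        # (c) second distinct event
        if len(events) >= 2:
            date = events[1]
            qualifying[pid] = min(qualifying.get(pid, date), date)
        # (b) loss strictly after a history-of-loss record
        if pid in hist_by_person.index:
            after = dates[dates > hist_by_person.loc[pid]]
            if len(after):
                date = after.iloc[0]
                qualifying[pid] = min(qualifying.get(pid, date), date)

    rows = [
        {
            "person_id": pid,
            "group": "rpl",
            "index_date": date,
            "n_distinct_losses": n_distinct.get(pid, 0),
        }
        for pid, date in qualifying.items()
    ]
    out = pd.DataFrame(rows, columns=["person_id", "group", "index_date", "n_distinct_losses"])
    return out.sort_values("person_id").reset_index(drop=True)


def select_controls(
    bundle: EhrBundle, concept_sets: dict[str, ConceptSet]
) -> pd.DataFrame:
    """Pre-exclusion controls: any live birth, zero exclusion records ever."""
    births = _conditions_in(bundle, concept_sets["live_birth"].concept_ids)
    excluded_pids = set(
        _conditions_in(bundle, concept_sets["control_exclusion"].concept_ids)["person_id"]
    )
    first_birth = births.groupby("person_id")["start_date"].min()
    first_birth = first_birth[~first_birth.index.isin(excluded_pids)]
    out = pd.DataFrame(
        {
            "person_id": first_birth.index,
            "group": "control",
            "index_date": first_birth.values,
            "n_distinct_losses": 0,
        }
    )
    return out.sort_values("person_id").reset_index(drop=True)


def _outcome_concept_ids(concept_sets: dict[str, ConceptSet]) -> set:
    ids: set = set()
    for cs in concept_sets.values():
        ids |= set(cs.concept_ids)
    return ids


def apply_exclusions(
    members: pd.DataFrame,
    bundle: EhrBundle,
    concept_sets: dict[str, ConceptSet],
    window_days: int = DEFAULT_WINDOW_DAYS,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the exclusion cascade in flowchart order and annotate covariates.

    Arms, in order: age at index outside [15, 44]; neither female nor any
    incident-pregnancy record; record span >= 100 years; no ICD diagnosis in
    the study window. ICD diagnoses are condition rows whose concept is not
    in any outcome concept set.
    """
    report = ExclusionReport()
    if members.empty:
        empty = pd.DataFrame(columns=COHORT_COLUMNS)
        return empty, report
    df = members.merge(bundle.persons, on="person_id", how="left")
    if df["birth_date"].isna().any():
        missing = df.loc[df["birth_date"].isna(), "person_id"].tolist()[:5]
        raise ValueError(f"members absent from person table: {missing}")

    def counts(frame):
        return frame.groupby("group").size().to_dict()

    report.initial = counts(df)

    df["age_at_index"] = (
        (df["index_date"] - df["birth_date"]).dt.days / DAYS_PER_YEAR
    )
    keep = (df["age_at_index"] >= 15) & (df["age_at_index"] <= 44)
    report.removed["age_out_of_range"] = counts(df[~keep])
    df = df[keep]

    incident = set(
        _conditions_in(bundle, concept_sets["incident_pregnancy"].concept_ids)["person_id"]
    )
    keep = (df["gender"] == "female") | df["person_id"].isin(incident)
    report.removed["gender_no_pregnancy"] = counts(df[~keep])
    df = df[keep]

    extents = bundle.conditions.groupby("person_id")["start_date"].agg(["min", "max"])
    visit_extents = bundle.visits.groupby("person_id")["visit_date"].agg(["min", "max"])
    extents = extents.join(visit_extents, how="outer", lsuffix="_c", rsuffix="_v")
    first = extents.filter(like="min").min(axis=1)
    last = extents.filter(like="max").max(axis=1)
    df = df.merge(
        pd.DataFrame({"first_record": first, "last_record": last}),
        left_on="person_id", right_index=True, how="left",
    )
    span_years = (df["last_record"] - df["first_record"]).dt.days / DAYS_PER_YEAR
    keep = span_years < 100
    report.removed["record_span_100y"] = counts(df[~keep])
    df = df[keep]

    outcome_ids = _outcome_concept_ids(concept_sets)
    icd = bundle.conditions[~bundle.conditions["concept_id"].isin(outcome_ids)]
    window_end = df.set_index("person_id")["index_date"] + pd.Timedelta(days=window_days)
    icd = icd[icd["person_id"].isin(window_end.index)]
    in_window = icd["start_date"] <= icd["person_id"].map(window_end)
    has_dx = set(icd.loc[in_window, "person_id"])
    keep = df["person_id"].isin(has_dx)
    report.removed["no_diagnoses"] = counts(df[~keep])
    df = df[keep].copy()

    # covariates for retained members
    visits = bundle.visits.merge(
        df[["person_id", "index_date"]], on="person_id", how="inner"
    )
    in_win = visits["visit_date"] <= visits["index_date"] + pd.Timedelta(days=window_days)
    n_visits = visits[in_win].groupby("person_id").size()
    df["n_visits_in_window"] = df["person_id"].map(n_visits).fillna(0).astype(int)
    win_end = df["index_date"] + pd.Timedelta(days=window_days)
    study_end = pd.concat([df["last_record"], win_end], axis=1).min(axis=1)
    df["ehr_years_in_window"] = (
        (study_end - df["first_record"]).dt.days / DAYS_PER_YEAR
    ).clip(lower=0)

    report.final = counts(df)
    df = df[COHORT_COLUMNS].sort_values(["group", "person_id"]).reset_index(drop=True)
    return df, report


def build_cohort(
    bundle: EhrBundle,
    concept_sets: dict[str, ConceptSet],
    window_days: int = DEFAULT_WINDOW_DAYS,
    min_gap_days: int = 90,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Main-analysis cohort: RPL cases + controls after exclusions.

    The two groups are disjoint by construction (controls exclude every
    patient with any loss record); this is asserted on every build.
    """
    rpl = select_rpl(bundle, concept_sets, min_gap_days)
    controls = select_controls(bundle, concept_sets)
    overlap = set(rpl["person_id"]) & set(controls["person_id"])
    if overlap:
        raise AssertionError(f"RPL and control groups overlap: {sorted(overlap)[:5]}")
    members = pd.concat([rpl, controls], ignore_index=True)
    return apply_exclusions(members, bundle, concept_sets, window_days)


def select_severe_rpl(
    bundle: EhrBundle,
    concept_sets: dict[str, ConceptSet],
    window_days: int = DEFAULT_WINDOW_DAYS,
    min_gap_days: int = 90,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Severe-RPL subgroup: >= 3 distinct loss events; index = third event.

    Controls are the same as in the main analysis.
    """
    loss_ids = concept_sets["pregnancy_loss"].concept_ids
    losses = _conditions_in(bundle, loss_ids)
    rows = []
    for pid, g in losses.groupby("person_id"):
        events = distinct_loss_events(list(g["start_date"].sort_values()), min_gap_days)
        if len(events) >= 3:
            rows.append(
                {
                    "person_id": pid,
                    "group": "rpl",
                    "index_date": events[2],
                    "n_distinct_losses": len(events),
                }
            )
    severe = pd.DataFrame(
        rows, columns=["person_id", "group", "index_date", "n_distinct_losses"]
    )
    controls = select_controls(bundle, concept_sets)
    members = pd.concat([severe, controls], ignore_index=True)
    return apply_exclusions(members, bundle, concept_sets, window_days)


def select_ten_year_subgroup(cohort: pd.DataFrame, bundle: EhrBundle) -> pd.DataFrame:
    """Members with >= 10 years (3652 days) of records before their index."""
    first = bundle.conditions.groupby("person_id")["start_date"].min()
    visit_first = bundle.visits.groupby("person_id")["visit_date"].min()
    first = pd.concat([first, visit_first]).groupby(level=0).min()
    earliest = cohort["person_id"].map(first)
    keep = earliest <= cohort["index_date"] - pd.Timedelta(days=TEN_YEARS_DAYS)
    return cohort[keep].reset_index(drop=True)


def find_next_outcome(
    rpl_cohort: pd.DataFrame,
    bundle: EhrBundle,
    concept_sets: dict[str, ConceptSet],
    min_days: int = 30,
) -> pd.DataFrame:
    """Earliest birth-or-loss outcome >= ``min_days`` after the RPL index.

    Patients with no subsequent outcome are omitted. A same-day birth+loss
    tie is classified as a loss and flagged ambiguous (conservative for the
    loss outcome).
    """
    cases = rpl_cohort[rpl_cohort["group"] == "rpl"]
    loss_ids = concept_sets["pregnancy_loss"].concept_ids
    birth_ids = concept_sets["live_birth"].concept_ids
    events = bundle.conditions[
        bundle.conditions["concept_id"].isin(loss_ids | birth_ids)
    ].copy()
    events["outcome"] = np.where(
        events["concept_id"].isin(list(loss_ids)), "loss", "birth"
    )
    events = events.merge(
        cases[["person_id", "index_date"]], on="person_id", how="inner"
    )
    events = events[
        events["start_date"] >= events["index_date"] + pd.Timedelta(days=min_days)
    ]
    rows = []
    for pid, g in events.groupby("person_id"):
        first_date = g["start_date"].min()
        at_first = g[g["start_date"] == first_date]
        kinds = set(at_first["outcome"])
        ambiguous = len(kinds) > 1
        outcome = "loss" if "loss" in kinds else "birth"
        rows.append(
            {
                "person_id": pid,
                "outcome": outcome,
                "outcome_date": first_date,
                "ambiguous": ambiguous,
            }
        )
    return pd.DataFrame(
        rows, columns=["person_id", "outcome", "outcome_date", "ambiguous"]
    ).sort_values("person_id").reset_index(drop=True)
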