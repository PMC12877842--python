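"""Windowed ICD extraction and Phecode-aggregated presence matrix.

The study window runs from the unbounded past through index date + 365 days
(inclusive): diagnoses recorded up to a year after RPL onset or first live
birth are retained because post-outcome diagnostic workups are informative.
ICD codes are aggregated to Phecodes (v1.2 crosswalk layout) and presence is
any-occurrence one-hot encoding; any Phecode carried by at least one cohort
member is a candidate diagnosis. ICD codes absent from the crosswalk are
counted in a coverage report, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cohort import DEFAULT_WINDOW_DAYS
from .ehr_io import EhrBundle, PhecodeMap, normalize_icd

PREGNANCY_CATEGORY = "pregnancy complications"


@dataclass
class PhenomeMatrix:
    """Patients x Phecodes presence indicators with per-group counts.

    ``patients``: (person_id, group, plus cohort covariates);
    ``presence``: binary DataFrame indexed by person_id, one column per
    candidate phecode; ``diagnoses``: per-column metadata and counts
    (phecode, phecode_string, category, n_rpl_with, n_control_with);
    ``coverage``: unmapped ICD code -> in-window occurrence count.
    """

    patients: pd.DataFrame
    presence: pd.DataFrame
    diagnoses: pd.DataFrame
    coverage: dict = field(default_factory=dict)

    @property
    def phecodes(self) -> list[str]:
        return list(self.presence.columns)

    def counts_for(self, phecode: str) -> tuple[int, int]:
        row = self.diagnoses.set_index("phecode").loc[phecode]
        return int(row["n_rpl_with"]), int(row["n_control_with"])

    def restrict_patients(self, person_ids) -> "PhenomeMatrix":
        """Sub-matrix for a patient subset; candidate columns are re-filtered
        and counts recomputed."""
        patients = self.patients[self.patients["person_id"].isin(set(person_ids))]
        presence = self.presence.loc[patients["person_id"]]
        keep = presence.columns[presence.sum(axis=0) >= 1]
        presence = presence[keep]
        diagnoses = _count_groups(presence, patients)
        meta = self.diagnoses.set_index("phecode")[["phecode_string", "category"]]
        diagnoses = diagnoses.join(meta, on="phecode")[
            ["phecode", "phecode_string", "category", "n_rpl_with", "n_control_with"]
        ]
        return PhenomeMatrix(patients.reset_index(drop=True), presence, diagnoses,
                             dict(self.coverage))


def extract_window_codes(
    member_index_date,
    conditions: pd.DataFrame,
    window_days: int = DEFAULT_WINDOW_DAYS,
) -> set[str]:
    """ICD codes for one member: any record dated <= index + window_days."""
    end = member_index_date + pd.Timedelta(days=window_days)
    return set(conditions.loc[conditions["start_date"] <= end, "concept_id"])


def _count_groups(presence: pd.DataFrame, patients: pd.DataFrame) -> pd.DataFrame:
    groups = patients.set_index("person_id")["group"]
    by_group = presence.groupby(groups.loc[presence.index]).sum()
    n_rpl = by_group.loc["rpl"] if "rpl" in by_group.index else 0
    n_ctl = by_group.loc["control"] if "control" in by_group.index else 0
    return pd.DataFrame(
        {
            "phecode": presence.columns,
            "n_rpl_with": pd.Series(n_rpl, index=presence.columns).fillna(0).astype(int).values,
            "n_control_with": pd.Series(n_ctl, index=presence.columns).fillna(0).astype(int).values,
        }
    )


def build_matrix(
    cohort: pd.DataFrame,
    bundle: EhrBundle,
    phecode_map: PhecodeMap,
    window_days: int = DEFAULT_WINDOW_DAYS,
    outcome_concept_ids: set | None = None,
) -> PhenomeMatrix:
    """Build the presence matrix for a cohort.

    Non-ICD outcome concepts (``outcome_concept_ids``) are ignored before
    crosswalk lookup; remaining unmapped codes land in the coverage report.
    """
    missing = set(cohort["person_id"]) - set(bundle.persons["person_id"])
    if missing:
        raise ValueError(f"cohort members absent from bundle: {sorted(missing)[:5]}")

    conds = bundle.conditions.merge(
        cohort[["person_id", "index_date"]], on="person_id", how="inner"
    )
    conds = conds[
        conds["start_date"] <= conds["index_date"] + pd.Timedelta(days=window_days)
    ]
    if outcome_concept_ids:
        conds = conds[~conds["concept_id"].isin(outcome_concept_ids)]

    codes = conds[["person_id", "concept_id"]].drop_duplicates()
    mapped_rows = []
    coverage: dict[str, int] = {}
    lookup_cache: dict[str, set] = {}
    for code in codes["concept_id"].unique():
        lookup_cache[code] = phecode_map.lookup(code)
    for pid, code in zip(codes["person_id"], codes["concept_id"]):
        phecodes = lookup_cache[code]
        if not phecodes:
            coverage[normalize_icd(code)] = coverage.get(normalize_icd(code), 0) + 1
            continue
        for ph in phecodes:
            mapped_rows.append((pid, ph))

    pairs = pd.DataFrame(mapped_rows, columns=["person_id", "phecode"]).drop_duplicates()
    presence = (
        pd.crosstab(pairs["person_id"], pairs["phecode"]).clip(upper=1).astype("int8")
    )
    # include cohort members with zero mapped diagnoses as all-zero rows
    presence = presence.reindex(cohort["person_id"], fill_value=0)
    presence.index.name = "person_id"
    presence = presence[sorted(presence.columns)]

    diagnoses = _count_groups(presence, cohort)
    meta = phecode_map.metadata().set_index("phecode")
    diagnoses["phecode_string"] = diagnoses["phecode"].map(meta["phecode_string"])
    diagnoses["category"] = diagnoses["phecode"].map(meta["category"])
    diagnoses = diagnoses[
        ["phecode", "phecode_string", "category", "n_rpl_with", "n_control_with"]
    ]
    return PhenomeMatrix(cohort.reset_index(drop=True), presence, diagnoses, coverage)


def drop_category(
    matrix: PhenomeMatrix, category: str = PREGNANCY_CATEGORY
) -> PhenomeMatrix:
    """Remove every column of the named Phecode category.

    Rows are retained even when they become all-zero (patients whose only
    diagnoses were in the dropped category stay in the matrix).
    """
    keep = matrix.diagnoses.loc[matrix.diagnoses["category"] != category, "phecode"]
    return PhenomeMatrix(
        matrix.patients,
        matrix.presence[list(keep)],
        matrix.diagnoses[matrix.diagnoses["phecode"].isin(set(keep))].reset_index(drop=True),
        dict(matrix.coverage),
    )
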