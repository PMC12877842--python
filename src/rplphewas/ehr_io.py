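"""OMOP-lite data model and delimited-text I/O.

The study operates on three flat tables per center — persons, condition
occurrences, and visit occurrences — plus two reference inputs: concept sets
defining pregnancy outcomes (loss, live birth, history-of-loss, RPL
diagnosis, control exclusions, incident pregnancy) and an ICD→Phecode
crosswalk in the Phecode map v1.2 column layout. Everything is interchanged
as CSV with named headers; dates are ISO-8601 calendar dates (time of day is
ignored — the analyses operate at day resolution).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

#: Allowed concept-set names, mirroring the outcome categories the study uses.
CONCEPT_SET_NAMES = (
    "rpl_diagnosis",
    "pregnancy_loss",
    "history_of_loss",
    "live_birth",
    "control_exclusion",
    "incident_pregnancy",
)

GENDER_LEVELS = ("female", "male", "other", "unknown")

PERSON_COLUMNS = ("person_id", "birth_date", "gender", "race", "ethnicity")
CONDITION_COLUMNS = ("person_id", "condition_concept_id", "condition_start_date")
VISIT_COLUMNS = ("person_id", "visit_start_date")


class FormatError(ValueError):
    """A required column is missing or a field cannot be parsed."""


@dataclass
class LoadReport:
    """Row-level accounting from :func:`read_bundle`."""

    n_persons: int = 0
    n_conditions: int = 0
    n_visits: int = 0
    n_orphan_conditions: int = 0
    n_orphan_visits: int = 0


@dataclass
class EhrBundle:
    """One center's EHR extract.

    ``persons`` has columns (person_id, birth_date, gender, race, ethnicity);
    ``conditions`` (person_id, concept_id, start_date);
    ``visits`` (person_id, visit_date). Dates are ``datetime64[ns]``.
    """

    center_label: str
    persons: pd.DataFrame
    conditions: pd.DataFrame
    visits: pd.DataFrame
    load_report: LoadReport | None = None

    def validate(self) -> None:
        if self.persons["person_id"].duplicated().any():
            dupes = self.persons.loc[self.persons["person_id"].duplicated(), "person_id"]
            raise ValueError(f"duplicate person_id values: {sorted(set(dupes))[:5]}")
        known = set(self.persons["person_id"])
        for name, table, col in (
            ("conditions", self.conditions, "person_id"),
            ("visits", self.visits, "person_id"),
        ):
            unknown = set(table[col]) - known
            if unknown:
                raise ValueError(
                    f"{name} reference unknown person_id values: {sorted(unknown)[:5]}"
                )


@dataclass(frozen=True)
class ConceptSet:
    name: str
    concept_ids: frozenset = field(default_factory=frozenset)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concept_ids


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    for col in columns:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")


def _parse_dates(df: pd.DataFrame, column: str, path) -> pd.Series:
    parsed = pd.to_datetime(df[column], format="ISO8601", errors="coerce")
    bad = parsed.isna() & df[column].notna()
    if bad.any():
        # header is line 1, so data row i is file line i + 2
        lines = [int(i) + 2 for i in df.index[bad][:5]]
        raise FormatError(
            f"{path}: unparseable date(s) in column '{column}' at line(s) {lines}"
        )
    return parsed.dt.normalize()


def read_bundle(
    person_path, condition_path, visit_path, center_label: str
) -> EhrBundle:
    """Read one center's person/condition/visit CSVs into a validated bundle.

    Condition and visit rows whose person_id is absent from the person table
    are dropped and counted in the bundle's :class:`LoadReport`.
    """
    persons = pd.read_csv(person_path, dtype=str)
    _require_columns(persons, PERSON_COLUMNS, person_path)
    persons = persons.loc[:, list(PERSON_COLUMNS)].copy()
    persons["birth_date"] = _parse_dates(persons, "birth_date", person_path)
    persons["gender"] = persons["gender"].fillna("unknown")
    persons["race"] = persons["race"].fillna("Unknown")
    persons["ethnicity"] = persons["ethnicity"].fillna("Unknown")

    conditions = pd.read_csv(condition_path, dtype=str)
    _require_columns(conditions, CONDITION_COLUMNS, condition_path)
    conditions = conditions.rename(
        columns={
            "condition_concept_id": "concept_id",
            "condition_start_date": "start_date",
        }
    )[["person_id", "concept_id", "start_date"]].copy()
    if conditions["concept_id"].isna().any() or (conditions["concept_id"] == "").any():
        raise FormatError(f"{condition_path}: empty concept_id")
    conditions["start_date"] = _parse_dates(conditions, "start_date", condition_path)

    visits = pd.read_csv(visit_path, dtype=str)
    _require_columns(visits, VISIT_COLUMNS, visit_path)
    visits = visits.rename(columns={"visit_start_date": "visit_date"})[
        ["person_id", "visit_date"]
    ].copy()
    visits["visit_date"] = _parse_dates(visits, "visit_date", visit_path)

    report = LoadReport(n_persons=len(persons))
    known = set(persons["person_id"])
    orphan_c = ~conditions["person_id"].isin(known)
    orphan_v = ~visits["person_id"].isin(known)
    report.n_orphan_conditions = int(orphan_c.sum())
    report.n_orphan_visits = int(orphan_v.sum())
    conditions = conditions.loc[~orphan_c].reset_index(drop=True)
    visits = visits.loc[~orphan_v].reset_index(drop=True)
    report.n_conditions = len(conditions)
    report.n_visits = len(visits)

    bundle = EhrBundle(center_label, persons, conditions, visits, load_report=report)
    bundle.validate()
    return bundle


def write_bundle(bundle: EhrBundle, out_dir) -> dict:
    """Write the three EHR CSVs under ``out_dir``; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "person": out_dir / "person.csv",
        "condition": out_dir / "condition_occurrence.csv",
        "visit": out_dir / "visit_occurrence.csv",
    }
    persons = bundle.persons.copy()
    persons["birth_date"] = persons["birth_date"].dt.strftime("%Y-%m-%d")
    persons.to_csv(paths["person"], index=False)

    conditions = bundle.conditions.rename(
        columns={"concept_id": "condition_concept_id", "start_date": "condition_start_date"}
    ).copy()
    conditions["condition_start_date"] = conditions["condition_start_date"].dt.strftime(
        "%Y-%m-%d"
    )
    conditions.to_csv(paths["condition"], index=False)

    visits = bundle.visits.rename(columns={"visit_date": "visit_start_date"}).copy()
    visits["visit_start_date"] = visits["visit_start_date"].dt.strftime("%Y-%m-%d")
    visits.to_csv(paths["visit"], index=False)
    return paths


def read_bundle_dir(bundle_dir, center_label: str | None = None) -> EhrBundle:
    bundle_dir = Path(bundle_dir)
    return read_bundle(
        bundle_dir / "person.csv",
        bundle_dir / "condition_occurrence.csv",
        bundle_dir / "visit_occurrence.csv",
        center_label or bundle_dir.name,
    )


def read_concept_sets(path) -> dict[str, ConceptSet]:
    """Read concept sets from a (set_name, concept_id, concept_name) CSV.

    Duplicate concept ids within a set collapse (set semantics); an unknown
    set_name raises, listing the allowed names.
    """
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ("set_name", "concept_id"), path)
    if df.empty:
        logger.warning("concept set file %s is empty", path)
        return {}
    unknown = set(df["set_name"]) - set(CONCEPT_SET_NAMES)
    if unknown:
        raise FormatError(
            f"{path}: unknown set_name(s) {sorted(unknown)}; "
            f"allowed names are {list(CONCEPT_SET_NAMES)}"
        )
    return {
        name: ConceptSet(name, frozenset(group["concept_id"]))
        for name, group in df.groupby("set_name", sort=True)
    }


def write_concept_sets(concept_sets: dict[str, ConceptSet], path) -> None:
    rows = [
        {"set_name": cs.name, "concept_id": cid, "concept_name": ""}
        for cs in concept_sets.values()
        for cid in sorted(cs.concept_ids)
    ]
    pd.DataFrame(rows, columns=["set_name", "concept_id", "concept_name"]).to_csv(
        path, index=False
    )


def normalize_icd(code: str) -> str:
    """Dot-insensitive, case-insensitive ICD code key ('E11.9' ≡ 'E119')."""
    return str(code).strip().upper().replace(".", "")


class PhecodeMap:
    """ICD→Phecode crosswalk (v1.2 column layout).

    Lookup is dot-insensitive so either ICD dialect matches. The
    (phecode → phecode_string, category) metadata must be consistent; a
    conflicting category for the same phecode is an error at load time.
    """

    def __init__(self, rows: pd.DataFrame):
        required = ("icd_code", "icd_flavor", "phecode", "phecode_string", "category")
        for col in required:
            if col not in rows.columns:
                raise FormatError(f"phecode map: missing required column '{col}'")
        rows = rows.loc[:, list(required)].drop_duplicates().reset_index(drop=True)
        rows["icd_flavor"] = rows["icd_flavor"].astype(int)
        if rows["category"].isna().any() or (rows["category"] == "").any():
            raise FormatError("phecode map: empty category for a mapped row")
        meta = rows[["phecode", "phecode_string", "category"]].drop_duplicates()
        conflicts = meta["phecode"][meta["phecode"].duplicated()]
        if len(conflicts):
            raise FormatError(
                "phecode map: conflicting phecode_string/category for phecode(s) "
                f"{sorted(set(conflicts))}"
            )
        self.rows = rows
        self._meta = meta.set_index("phecode")
        self._lookup: dict[str, set[str]] = {}
        for code, phecode in zip(rows["icd_code"], rows["phecode"]):
            self._lookup.setdefault(normalize_icd(code), set()).add(phecode)

    def lookup(self, icd_code: str) -> set[str]:
        """Phecodes for an ICD code (empty set if unmapped)."""
        return set(self._lookup.get(normalize_icd(icd_code), ()))

    def phecode_string(self, phecode: str) -> str:
        return str(self._meta.loc[phecode, "phecode_string"])

    def category(self, phecode: str) -> str:
        return str(self._meta.loc[phecode, "category"])

    @property
    def phecodes(self) -> set[str]:
        return set(self._meta.index)

    def metadata(self) -> pd.DataFrame:
        """(phecode, phecode_string, category) table."""
        return self._meta.reset_index()


def read_phecode_map(path) -> PhecodeMap:
    return PhecodeMap(pd.read_csv(path, dtype=str))


def bundled_phecode_map() -> PhecodeMap:
    """The small crosswalk fixture shipped with the package."""
    return read_phecode_map(Path(__file__).parent / "data" / "phecode_map_v1_2.csv")
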