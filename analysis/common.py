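"""Shared paths and loaders for the numbered analysis scripts.

The scripts form a chain: 01 writes the synthetic two-center bundles, later
steps read the previous step's CSVs, so each stage can also be pointed at a
real OMOP-style extract with the same layout.
"""

from pathlib import Path

import pandas as pd

from rplphewas import synth
from rplphewas.ehr_io import bundled_phecode_map, read_bundle_dir

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "analysis"
CENTERS = ("center-A", "center-B")

DATE_COLUMNS = ["index_date", "first_record", "last_record"]


def center_dir(label: str) -> Path:
    d = OUT / label
    d.mkdir(parents=True, exist_ok=True)
    return d


def load_bundle(label: str):
    return read_bundle_dir(center_dir(label) / "bundle", label)


def load_cohort(label: str) -> pd.DataFrame:
    return pd.read_csv(center_dir(label) / "cohort.csv", parse_dates=DATE_COLUMNS)


def load_matrix(label: str):
    """Rebuild the presence matrix from the stored bundle + cohort."""
    from rplphewas.phenome import build_matrix

    cs = synth.default_concept_sets()
    outcome_ids = {cid for s in cs.values() for cid in s.concept_ids}
    return build_matrix(load_cohort(label), load_bundle(label),
                        bundled_phecode_map(), outcome_concept_ids=outcome_ids)


def load_results(label: str, name: str) -> pd.DataFrame:
    return pd.read_csv(center_dir(label) / name, dtype={"phecode": str})
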