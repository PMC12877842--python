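"""Subgroup analyses: severe RPL (>=3 distinct losses) and >=10-year EHRs."""

from common import CENTERS, center_dir, load_bundle, load_cohort, load_matrix
from rplphewas import synth
from rplphewas.association import format_for_export, run_phewas
from rplphewas.cohort import select_severe_rpl, select_ten_year_subgroup
from rplphewas.ehr_io import bundled_phecode_map
from rplphewas.phenome import build_matrix


def main():
    cs = synth.default_concept_sets()
    outcome_ids = {cid for s in cs.values() for cid in s.concept_ids}
    for label in CENTERS:
        bundle = load_bundle(label)
        out = center_dir(label)

        severe, _ = select_severe_rpl(bundle, cs)
        n_sev = (severe["group"] == "rpl").sum()
        if n_sev:
            matrix = build_matrix(severe, bundle, bundled_phecode_map(),
                                  outcome_concept_ids=outcome_ids)
            res = run_phewas(matrix)
            format_for_export(res).to_csv(out / "associations_severe.csv", index=False)
            print(f"{label}: severe subgroup {n_sev} cases, "
                  f"{(res['direction'] != 'null').sum()} significant")

        cohort = load_cohort(label)
        sub = select_ten_year_subgroup(cohort, bundle)
        if (sub["group"] == "rpl").sum() and (sub["group"] == "control").sum():
            matrix = load_matrix(label).restrict_patients(sub["person_id"])
            res = run_phewas(matrix)
            format_for_export(res).to_csv(out / "associations_ten_year.csv",
                                          index=False)
            print(f"{label}: 10-year subgroup {len(sub)} members, "
                  f"{(res['direction'] != 'null').sum()} significant")


if __name__ == "__main__":
    main()
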