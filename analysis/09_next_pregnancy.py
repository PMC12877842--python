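"""Next-pregnancy analysis: do RPL-associated diagnoses predict the outcome
(loss vs birth) of cases' next recorded pregnancy?"""

from common import CENTERS, center_dir, load_bundle, load_cohort, load_matrix
from rplphewas import synth
from rplphewas.association import format_for_export, run_phewas
from rplphewas.cohort import find_next_outcome
from rplphewas.ehr_io import bundled_phecode_map
from rplphewas.nextpreg import run_next_pregnancy


def main():
    cs = synth.default_concept_sets()
    for label in CENTERS:
        bundle = load_bundle(label)
        cohort = load_cohort(label)
        res_main = run_phewas(load_matrix(label))
        validated = res_main.loc[res_main["direction"] != "null",
                                 ["phecode", "direction"]]
        outcomes = find_next_outcome(cohort, bundle, cs)
        if validated.empty or outcomes.empty:
            print(f"{label}: nothing to test")
            continue
        res = run_next_pregnancy(cohort, outcomes, bundle, bundled_phecode_map(),
                                 validated)
        out = center_dir(label)
        format_for_export(res).to_csv(out / "next_pregnancy_results.csv", index=False)
        n_loss = (outcomes["outcome"] == "loss").sum()
        conc = res.loc[res["converged"], "concordant_with_main"].mean()
        print(f"{label}: {len(outcomes)} next outcomes ({n_loss} losses); "
              f"{(res['direction'] != 'null').sum()} significant; "
              f"{conc:.0%} direction-concordant with the main analysis")


if __name__ == "__main__":
    main()
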