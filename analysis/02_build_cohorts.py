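"""Select RPL cases and live-birth controls at each center.

Applies the selection criteria (RPL diagnosis, history-then-loss, or two
losses >=90 days apart; controls with a live birth and no exclusion
records) and the exclusion cascade, and writes the cohort table plus the
flowchart-style exclusion report.
"""

from common import CENTERS, center_dir, load_bundle
from rplphewas import synth
from rplphewas.cohort import build_cohort


def main():
    cs = synth.default_concept_sets()
    for label in CENTERS:
        bundle = load_bundle(label)
        cohort, report = build_cohort(bundle, cs)
        out = center_dir(label)
        cohort.to_csv(out / "cohort.csv", index=False)
        report.to_frame().to_csv(out / "exclusion_report.csv", index=False)
        n_rpl = (cohort["group"] == "rpl").sum()
        n_ctl = (cohort["group"] == "control").sum()
        print(f"{label}: {n_rpl} RPL, {n_ctl} controls "
              f"(from {sum(report.initial.values())} selected; "
              f"removed {report.to_frame().iloc[1:-1].drop(columns='stage').to_numpy().sum():.0f})")


if __name__ == "__main__":
    main()
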