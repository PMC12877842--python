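"""Simulate the two study centers.

Center A has a near-equal case/control visit gap; center B has a large gap
(cases ~2.2x the control visit mean). Both share the planted diagnosis
panel, a +3-year case age shift with post-35 acceleration, and a positive
visit-count link to diagnosis intensity, so the downstream sensitivity
analysis has a real confounding signal to find.
"""

import argparse

from common import CENTERS, center_dir
from rplphewas import synth
from rplphewas.ehr_io import write_bundle, write_concept_sets
from rplphewas.pipeline import _subseeds


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-rpl", type=int, default=1200)
    parser.add_argument("--n-control", type=int, default=3600)
    args = parser.parse_args()

    seeds = _subseeds(args.seed, 2)
    makers = {"center-A": synth.ucsf_like_config,
              "center-B": synth.stanford_like_config}
    for label, sub_seed in zip(CENTERS, seeds):
        cfg = makers[label](seed=sub_seed, n_rpl=args.n_rpl,
                            n_control=args.n_control,
                            utilization_link_strength=1.1)
        bundle, truth = synth.generate_center(cfg)
        out = center_dir(label)
        write_bundle(bundle, out / "bundle")
        write_concept_sets(synth.default_concept_sets(),
                           out / "bundle" / "concept_sets.csv")
        truth.to_json(out / "ground_truth.json")
        pats = truth.patients
        gap = (pats.loc[pats["group"] == "rpl", "n_visits"].median(),
               pats.loc[pats["group"] == "control", "n_visits"].median())
        print(f"{label}: {len(bundle.persons)} persons, "
              f"{len(bundle.conditions)} condition rows; "
              f"median visits rpl/control = {gap[0]:.0f}/{gap[1]:.0f}")


if __name__ == "__main__":
    main()
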