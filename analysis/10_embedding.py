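"""UMAP of non-pregnancy diagnosis profiles with group rank-sum tests."""

import argparse

import numpy as np

from common import CENTERS, center_dir, load_matrix
from rplphewas.embed import embed_patients
from rplphewas.phenome import drop_category


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--max-patients", type=int, default=2000)
    args = parser.parse_args()

    for label in CENTERS:
        matrix = drop_category(load_matrix(label))
        if len(matrix.patients) > args.max_patients:
            rng = np.random.default_rng(args.seed)
            keep = rng.choice(matrix.patients["person_id"], args.max_patients,
                              replace=False)
            matrix = matrix.restrict_patients(keep)
        emb = embed_patients(matrix, seed=args.seed)
        out = center_dir(label)
        emb.coords.to_csv(out / "embedding.csv", index=False)
        emb.tests.to_csv(out / "embedding_tests.csv", index=False)
        group_p = emb.tests.loc[emb.tests["comparison"] == "rpl_vs_control", "p"]
        print(f"{label}: embedded {len(emb.coords)} patients; "
              f"RPL-vs-control rank-sum p per dimension: "
              + ", ".join(f"{p:.2g}" for p in group_p))


if __name__ == "__main__":
    main()
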