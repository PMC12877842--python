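"""Cross-center concordance of the main and sensitivity analyses.

Shared candidates are classed validated positive/negative, discordant,
single-center-only, or neither, and ORs are rank-correlated over the
both-significant set.
"""

from common import OUT, load_matrix
from rplphewas.association import run_phewas, ModelSpec
from rplphewas.compare import compare_centers


def main():
    results, results_sens = {}, {}
    for label in ("center-A", "center-B"):
        matrix = load_matrix(label)
        results[label] = run_phewas(matrix)
        results_sens[label] = run_phewas(matrix, spec=ModelSpec(include_visits=True))

    for name, pair in (("concordance", results), ("concordance_sensitivity",
                                                  results_sens)):
        conc = compare_centers(pair["center-A"], pair["center-B"])
        conc.to_csv(OUT / f"{name}.csv", index=False)
        counts = conc["class"].value_counts()
        print(f"{name}: {counts.get('validated_positive', 0)} validated positive, "
              f"{counts.get('validated_negative', 0)} validated negative, "
              f"{counts.get('discordant', 0)} discordant; "
              f"Spearman r = {conc.attrs['spearman_r']:.3f}")


if __name__ == "__main__":
    main()
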