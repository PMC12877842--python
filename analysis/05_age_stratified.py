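"""Age-stratified analysis: <35 vs 35+ at index.

Separate sweeps per stratum, the union comparison of significant results,
and two-sided z-tests of the per-diagnosis coefficients.
"""

from common import CENTERS, center_dir, load_matrix
from rplphewas.association import format_for_export
from rplphewas.compare import compare_within, stratify_and_test


def main():
    for label in CENTERS:
        matrix = load_matrix(label)
        ry, ro, ztests = stratify_and_test(matrix)
        out = center_dir(label)
        format_for_export(ry).to_csv(out / "associations_under35.csv", index=False)
        format_for_export(ro).to_csv(out / "associations_over35.csv", index=False)
        ztests.to_csv(out / "strata_comparison.csv", index=False)
        union = compare_within(ry, ro)
        union.to_csv(out / "loglog_under35_vs_over35.csv", index=False)
        if len(union):
            frac = (union["or_value_main"] > union["or_value_variant"]).mean()
            print(f"{label}: {len(union)} diagnoses significant in either stratum; "
                  f"{frac:.0%} have higher OR in <35; "
                  f"{(ztests['p_adj'] < 0.05).sum()} significant z-tests")


if __name__ == "__main__":
    main()
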