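"""Main association analysis: one adjusted model per candidate diagnosis.

Each candidate is tested with the additive logistic model (age smooth +
race + ethnicity), BH-corrected within the family; small-cell results are
redacted to directional bounds in the exported tables.
"""

from common import CENTERS, center_dir, load_matrix
from rplphewas.association import format_for_export, plot_table, run_phewas


def main():
    for label in CENTERS:
        matrix = load_matrix(label)
        res = run_phewas(matrix)
        out = center_dir(label)
        format_for_export(res).to_csv(out / "associations_main.csv", index=False)
        plot_table(res).to_csv(out / "plot_main.csv", index=False)
        pos = (res["direction"] == "positive").sum()
        neg = (res["direction"] == "negative").sum()
        print(f"{label}: {len(res)} tested, {pos} positive and {neg} negative "
              f"at BH-adjusted p < 0.05 ({res['redacted'].sum()} redacted)")


if __name__ == "__main__":
    main()
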