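"""Build the Phecode presence matrices.

Windowed ICD codes (unbounded past through index + 365 days) are aggregated
to Phecodes; per-diagnosis carrier counts by group and the unmapped-code
coverage report are written per center.
"""

import json

from common import CENTERS, center_dir, load_matrix


def main():
    for label in CENTERS:
        matrix = load_matrix(label)
        out = center_dir(label)
        matrix.diagnoses.to_csv(out / "diagnosis_counts.csv", index=False)
        (out / "coverage_report.json").write_text(json.dumps(matrix.coverage, indent=2))
        print(f"{label}: {len(matrix.phecodes)} candidate diagnoses over "
              f"{len(matrix.patients)} patients; "
              f"{sum(matrix.coverage.values())} unmapped code occurrences")


if __name__ == "__main__":
    main()
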