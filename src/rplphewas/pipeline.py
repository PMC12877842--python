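"""End-to-end orchestration: synthesize two centers, run every analysis.

``run_all`` mirrors the full study design: per center it builds the cohort
(with the exclusion-cascade report), the Phecode presence matrix, the main
PheWAS, the age-stratified and utilization-sensitivity analyses, the
severe-RPL and 10-year subgroup sweeps, the next-pregnancy analysis, and
the non-pregnancy UMAP; across centers it computes concordance for the main
and sensitivity analyses. Every stage writes a CSV under the output
directory and a run manifest records seeds, sizes, and row counts. A
failing analysis is reported in the manifest; the others still complete.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import synth
from .association import ModelSpec, format_for_export, plot_table, run_phewas
from .cohort import build_cohort, find_next_outcome, select_severe_rpl, select_ten_year_subgroup
from .compare import compare_centers, compare_within, stratify_and_test, utilization_sensitivity
from .ehr_io import bundled_phecode_map, write_bundle, write_concept_sets
from .embed import embed_patients
from .nextpreg import run_next_pregnancy
from .phenome import build_matrix, drop_category

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str = "results/run"
    seed: int = 0
    n_rpl: int = 1200
    n_control: int = 3600
    window_days: int = 365
    redaction_threshold: int = 10
    age_df: int = 4
    utilization_link_strength: float = 0.8
    embed_max_patients: int = 2000
    analyses: dict = field(default_factory=lambda: {
        "main": True, "strata": True, "sensitivity": True, "severe": True,
        "ten_year": True, "next_pregnancy": True, "embedding": True,
        "concordance": True,
    })

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        data = tomllib.loads(Path(path).read_text())
        cfg = cls()
        for key, value in data.items():
            if key == "analyses":
                cfg.analyses.update(value)
            elif hasattr(cfg, key):
                setattr(cfg, key, value)
            else:
                raise ValueError(f"unknown config key '{key}'")
        return cfg


def _subseeds(seed: int, n: int) -> list[int]:
    # independent child seeds, kept below 2**31 for portability
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def run_all(config: RunConfig) -> dict:
    """Run the full two-center study; returns the manifest dict."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = _subseeds(config.seed, 4)
    spec = ModelSpec(age_df=config.age_df,
                     redaction_threshold=config.redaction_threshold)
    manifest: dict = {"seed": config.seed, "analyses": {}, "errors": {}}
    (out_dir / "config.json").write_text(json.dumps(asdict(config), indent=2))

    centers = {
        "center-A": synth.ucsf_like_config(
            seed=seeds[0], n_rpl=config.n_rpl, n_control=config.n_control,
            utilization_link_strength=config.utilization_link_strength,
        ),
        "center-B": synth.stanford_like_config(
            seed=seeds[1], n_rpl=config.n_rpl, n_control=config.n_control,
            utilization_link_strength=config.utilization_link_strength,
        ),
    }
    phecode_map = bundled_phecode_map()
    concept_sets = synth.default_concept_sets()
    all_concepts = {cid for cs in concept_sets.values() for cid in cs.concept_ids}

    results_main: dict[str, pd.DataFrame] = {}
    results_sens: dict[str, pd.DataFrame] = {}

    for label, center_cfg in centers.items():
        cdir = out_dir / label
        cdir.mkdir(exist_ok=True)
        bundle, truth = synth.generate_center(center_cfg)
        write_bundle(bundle, cdir / "bundle")
        write_concept_sets(concept_sets, cdir / "bundle" / "concept_sets.csv")
        truth.to_json(cdir / "ground_truth.json")

        cohort, report = build_cohort(bundle, concept_sets, config.window_days)
        cohort.to_csv(cdir / "cohort.csv", index=False)
        report.to_frame().to_csv(cdir / "exclusion_report.csv", index=False)
        matrix = build_matrix(cohort, bundle, phecode_map, config.window_days,
                              outcome_concept_ids=all_concepts)
        matrix.diagnoses.to_csv(cdir / "diagnosis_counts.csv", index=False)
        manifest["analyses"][f"{label}/cohort"] = {
            "n_rpl": int((cohort["group"] == "rpl").sum()),
            "n_control": int((cohort["group"] == "control").sum()),
            "n_candidates": len(matrix.phecodes),
        }

        def _stage(name, fn):
            if not config.analyses.get(name, True):
                return None
            try:
                return fn()
            except Exception as exc:  # isolate failures per analysis
                logger.exception("analysis %s failed at %s", name, label)
                manifest["errors"][f"{label}/{name}"] = repr(exc)
                return None

        def _main():
            res = run_phewas(matrix, spec=spec)
            format_for_export(res).to_csv(cdir / "associations_main.csv", index=False)
            plot_table(res).to_csv(cdir / "plot_main.csv", index=False)
            manifest["analyses"][f"{label}/main"] = {
                "n_tested": len(res),
                "n_significant": int((res["direction"] != "null").sum()),
            }
            return res

        res = _stage("main", _main)
        if res is not None:
            results_main[label] = res

        def _strata():
            ry, ro, comparison = stratify_and_test(matrix, spec=spec)
            format_for_export(ry).to_csv(cdir / "associations_under35.csv", index=False)
            format_for_export(ro).to_csv(cdir / "associations_over35.csv", index=False)
            comparison.to_csv(cdir / "strata_comparison.csv", index=False)
            union = compare_within(ry, ro)
            union.to_csv(cdir / "loglog_under35_vs_over35.csv", index=False)
            manifest["analyses"][f"{label}/strata"] = {
                "n_tested_both": len(comparison),
                "n_hetero_significant": int((comparison["p_adj"] < 0.05).sum()),
                "n_union_significant": len(union),
                "frac_higher_under35": float(
                    (union["or_value_main"] > union["or_value_variant"]).mean()
                ) if len(union) else None,
            }

        _stage("strata", _strata)

        def _sensitivity():
            sens = utilization_sensitivity(matrix, spec=spec)
            sens.per_diagnosis.to_csv(cdir / "sensitivity_per_diagnosis.csv", index=False)
            pd.DataFrame([{
                "median_pct_change": sens.median_pct_change,
                "n_union_significant": len(sens.union_significant),
                "n_excluded_nonconverged": sens.n_excluded_nonconverged,
            }]).to_csv(cdir / "sensitivity_summary.csv", index=False)
            format_for_export(sens.results_with).to_csv(
                cdir / "associations_with_visits.csv", index=False
            )
            union = compare_within(sens.results_without, sens.results_with)
            union.to_csv(cdir / "loglog_main_vs_sensitivity.csv", index=False)
            manifest["analyses"][f"{label}/sensitivity"] = {
                "median_pct_change": sens.median_pct_change,
                "n_union_significant": len(sens.union_significant),
            }
            results_sens[label] = sens.results_with

        _stage("sensitivity", _sensitivity)

        def _severe():
            severe_cohort, severe_report = select_severe_rpl(
                bundle, concept_sets, config.window_days
            )
            severe_matrix = build_matrix(
                severe_cohort, bundle, phecode_map, config.window_days,
                outcome_concept_ids=all_concepts,
            )
            res_sev = run_phewas(severe_matrix, spec=spec)
            format_for_export(res_sev).to_csv(cdir / "associations_severe.csv", index=False)
            manifest["analyses"][f"{label}/severe"] = {
                "n_rpl": int((severe_cohort["group"] == "rpl").sum()),
                "n_significant": int((res_sev["direction"] != "null").sum()),
            }

        _stage("severe", _severe)

        def _ten_year():
            sub = select_ten_year_subgroup(cohort, bundle)
            if (sub["group"] == "rpl").sum() == 0 or (sub["group"] == "control").sum() == 0:
                manifest["analyses"][f"{label}/ten_year"] = {
                    "n_members": len(sub), "note": "subgroup lacks both groups"
                }
                return
            sub_matrix = matrix.restrict_patients(sub["person_id"])
            res_sub = run_phewas(sub_matrix, spec=spec)
            format_for_export(res_sub).to_csv(cdir / "associations_ten_year.csv", index=False)
            manifest["analyses"][f"{label}/ten_year"] = {
                "n_members": len(sub),
                "n_significant": int((res_sub["direction"] != "null").sum()),
            }

        _stage("ten_year", _ten_year)

        def _next_pregnancy():
            if label not in results_main:
                return
            outcomes = find_next_outcome(cohort, bundle, concept_sets)
            validated = results_main[label].loc[
                results_main[label]["direction"] != "null", ["phecode", "direction"]
            ]
            if validated.empty or outcomes.empty:
                manifest["analyses"][f"{label}/next_pregnancy"] = {
                    "n_outcomes": len(outcomes), "note": "nothing to test"
                }
                return
            res_np = run_next_pregnancy(
                cohort, outcomes, bundle, phecode_map, validated, spec
            )
            format_for_export(res_np).to_csv(
                cdir / "next_pregnancy_results.csv", index=False
            )
            manifest["analyses"][f"{label}/next_pregnancy"] = {
                "n_outcomes": len(outcomes),
                "n_loss": int((outcomes["outcome"] == "loss").sum()),
                "n_birth": int((outcomes["outcome"] == "birth").sum()),
                "n_significant": int((res_np["direction"] != "null").sum()),
            }

        _stage("next_pregnancy", _next_pregnancy)

        def _embedding():
            nonpreg = drop_category(matrix)
            sub_matrix = nonpreg
            if len(nonpreg.patients) > config.embed_max_patients:
                rng = np.random.default_rng(seeds[2])
                keep = rng.choice(
                    nonpreg.patients["person_id"], config.embed_max_patients,
                    replace=False,
                )
                sub_matrix = nonpreg.restrict_patients(keep)
            emb = embed_patients(sub_matrix, seed=seeds[2])
            emb.coords.to_csv(cdir / "embedding.csv", index=False)
            emb.tests.to_csv(cdir / "embedding_tests.csv", index=False)
            manifest["analyses"][f"{label}/embedding"] = {
                "n_embedded": len(emb.coords), **emb.params,
            }

        _stage("embedding", _embedding)

    if config.analyses.get("concordance", True) and len(results_main) == 2:
        try:
            a, b = (results_main[k] for k in ("center-A", "center-B"))
            conc = compare_centers(a, b)
            conc.to_csv(out_dir / "concordance.csv", index=False)
            manifest["analyses"]["concordance"] = {
                "n_shared": len(conc),
                "n_validated_positive": int((conc["class"] == "validated_positive").sum()),
                "n_validated_negative": int((conc["class"] == "validated_negative").sum()),
                "n_discordant": int((conc["class"] == "discordant").sum()),
                "spearman_r": conc.attrs["spearman_r"],
            }
            if len(results_sens) == 2:
                conc_s = compare_centers(
                    results_sens["center-A"], results_sens["center-B"]
                )
                conc_s.to_csv(out_dir / "concordance_sensitivity.csv", index=False)
                manifest["analyses"]["concordance_sensitivity"] = {
                    "n_validated_positive": int(
                        (conc_s["class"] == "validated_positive").sum()
                    ),
                    "n_validated_negative": int(
                        (conc_s["class"] == "validated_negative").sum()
                    ),
                    "spearman_r": conc_s.attrs["spearman_r"],
                }
        except Exception as exc:
            logger.exception("concordance failed")
            manifest["errors"]["concordance"] = repr(exc)

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
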