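"""Age-stratified, utilization-sensitivity, and concordance analyses.

* Age strata: separate PheWAS sweeps for patients <35 and 35+ at index,
  restricted to diagnoses carried in both strata, then a two-sided z-test
  per diagnosis on the coefficient difference,
  z = (b_young - b_old) / sqrt(se_young^2 + se_old^2), BH-adjusted.
* Utilization sensitivity: paired sweeps without/with the visit-count
  covariate; per-diagnosis percent change of the adjusted OR,
  100 * (or_with - or_without) / or_without (negative = attenuation toward
  the null), summarized by the median over the union of significant sets.
* Cross-center concordance: each diagnosis tested at both centers is
  classed validated_positive / validated_negative / discordant /
  single_center_only / neither; Spearman rank correlation of ORs over the
  both-significant set; a >=10-patient filter marks plot-eligible rows.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .association import ALPHA, ModelSpec, bh_adjust, run_phewas

AGE_CUTOFF = 35.0


def stratify_and_test(
    matrix, spec: ModelSpec | None = None, cutoff: float = AGE_CUTOFF
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run the <cutoff and >=cutoff sweeps and z-test each shared coefficient.

    Returns (results_young, results_old, comparison). Only candidates
    carried by at least one patient in *both* strata are tested; a stratum
    with zero cases or zero controls is an error.
    """
    spec = spec or ModelSpec()
    patients = matrix.patients
    young_ids = patients.loc[patients["age_at_index"] < cutoff, "person_id"]
    old_ids = patients.loc[patients["age_at_index"] >= cutoff, "person_id"]
    m_young = matrix.restrict_patients(young_ids)
    m_old = matrix.restrict_patients(old_ids)
    for name, m in (("<35", m_young), ("35+", m_old)):
        groups = set(m.patients["group"])
        if groups != {"rpl", "control"}:
            raise ValueError(f"stratum {name} lacks cases or controls: {groups}")

    shared = sorted(set(m_young.phecodes) & set(m_old.phecodes))
    m_young.presence = m_young.presence[shared]
    m_young.diagnoses = m_young.diagnoses[m_young.diagnoses["phecode"].isin(shared)]
    m_old.presence = m_old.presence[shared]
    m_old.diagnoses = m_old.diagnoses[m_old.diagnoses["phecode"].isin(shared)]

    res_young = run_phewas(m_young, spec=spec)
    res_old = run_phewas(m_old, spec=spec)

    comparison = coefficient_z_tests(res_young, res_old)
    return res_young, res_old, comparison


def coefficient_z_tests(
    res_young: pd.DataFrame, res_old: pd.DataFrame
) -> pd.DataFrame:
    """Two-sided z-tests of stratum coefficients, BH over the family."""
    merged = res_young.merge(
        res_old, on="phecode", suffixes=("_young", "_old"), how="inner"
    )
    ok = merged["converged_young"] & merged["converged_old"]
    merged = merged[ok].reset_index(drop=True)
    z = (merged["beta_young"] - merged["beta_old"]) / np.sqrt(
        merged["se_young"] ** 2 + merged["se_old"] ** 2
    )
    p = 2 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame(
        {
            "phecode": merged["phecode"],
            "beta_young": merged["beta_young"],
            "se_young": merged["se_young"],
            "beta_old": merged["beta_old"],
            "se_old": merged["se_old"],
            "z": z,
            "p": p,
            "p_adj": bh_adjust(p),
        }
    )
    out["higher_stratum"] = np.where(
        out["z"] > 0, "under35", np.where(out["z"] < 0, "over35", "tie")
    )
    return out


@dataclass
class SensitivitySummary:
    per_diagnosis: pd.DataFrame  # phecode, or_without, or_with, pct_change, in_union
    median_pct_change: float
    union_significant: set
    n_excluded_nonconverged: int
    results_without: pd.DataFrame | None = None
    results_with: pd.DataFrame | None = None


def utilization_sensitivity(
    matrix, spec: ModelSpec | None = None
) -> SensitivitySummary:
    """Paired sweeps without/with the visit-count covariate.

    ``pct_change`` = 100 * (or_with - or_without) / or_without; the median is
    taken over the union of significant diagnoses from both fits, excluding
    non-converged pairs (counted separately).
    """
    spec = spec or ModelSpec()
    spec_without = ModelSpec(**{**vars(spec), "include_visits": False})
    spec_with = ModelSpec(**{**vars(spec), "include_visits": True})
    res_without = run_phewas(matrix, spec=spec_without)
    res_with = run_phewas(matrix, spec=spec_with)

    merged = res_without.merge(
        res_with[["phecode", "or_value", "p_adj", "converged", "direction"]],
        on="phecode", suffixes=("_without", "_with"),
    )
    merged["pct_change"] = 100.0 * (
        merged["or_value_with"] - merged["or_value_without"]
    ) / merged["or_value_without"]
    sig_without = merged["p_adj_without"] < spec.alpha
    sig_with = merged["p_adj_with"] < spec.alpha
    merged["in_union"] = sig_without | sig_with
    converged = merged["converged_without"] & merged["converged_with"]
    pool = merged[merged["in_union"] & converged]
    per_dx = merged[
        ["phecode", "or_value_without", "or_value_with", "pct_change", "in_union"]
    ].rename(columns={"or_value_without": "or_without", "or_value_with": "or_with"})
    return SensitivitySummary(
        per_diagnosis=per_dx,
        median_pct_change=float(pool["pct_change"].median()) if len(pool) else np.nan,
        union_significant=set(merged.loc[merged["in_union"], "phecode"]),
        n_excluded_nonconverged=int((merged["in_union"] & ~converged).sum()),
        results_without=res_without,
        results_with=res_with,
    )


def pct_change(or_without: float, or_with: float) -> float:
    return 100.0 * (or_with - or_without) / or_without


CONCORDANCE_CLASSES = (
    "validated_positive", "validated_negative", "discordant",
    "single_center_only", "neither",
)


def compare_centers(
    results_a: pd.DataFrame, results_b: pd.DataFrame, alpha: float = ALPHA
) -> pd.DataFrame:
    """Classify every shared candidate and correlate ORs across centers.

    The classes partition the shared-candidate set. Spearman is computed on
    ORs over the both-significant subset (it is rank-invariant to the log
    transform). ``plot_filter`` marks diagnoses carried by >=10 patients in
    either group at both centers.
    """
    merged = results_a.merge(
        results_b, on="phecode", suffixes=("_a", "_b"), how="inner"
    )
    if merged.empty:
        raise ValueError("no shared candidate diagnoses between centers")
    sig_a = (merged["p_adj_a"] < alpha) & merged["converged_a"]
    sig_b = (merged["p_adj_b"] < alpha) & merged["converged_b"]
    pos_a = merged["or_value_a"] > 1
    pos_b = merged["or_value_b"] > 1
    klass = np.select(
        [
            sig_a & sig_b & (pos_a == pos_b) & pos_a,
            sig_a & sig_b & (pos_a == pos_b) & ~pos_a,
            sig_a & sig_b & (pos_a != pos_b),
            sig_a ^ sig_b,
        ],
        ["validated_positive", "validated_negative", "discordant",
         "single_center_only"],
        default="neither",
    )
    out = merged[
        ["phecode", "or_value_a", "p_adj_a", "or_value_b", "p_adj_b",
         "n_rpl_with_a", "n_control_with_a", "n_rpl_with_b", "n_control_with_b"]
    ].copy()
    if "phecode_string_a" in merged:
        out.insert(1, "phecode_string", merged["phecode_string_a"])
    out["class"] = klass
    out["plot_filter"] = (
        (merged[["n_rpl_with_a", "n_control_with_a"]].max(axis=1) >= 10)
        & (merged[["n_rpl_with_b", "n_control_with_b"]].max(axis=1) >= 10)
    )
    both = out[(np.isin(klass, ["validated_positive", "validated_negative",
                                "discordant"]))]
    if len(both) >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r, p = stats.spearmanr(both["or_value_a"], both["or_value_b"])
        out.attrs["spearman_r"], out.attrs["spearman_p"] = float(r), float(p)
    else:
        out.attrs["spearman_r"] = out.attrs["spearman_p"] = np.nan
    return out


def compare_within(
    results_main: pd.DataFrame, results_variant: pd.DataFrame, alpha: float = ALPHA
) -> pd.DataFrame:
    """Union comparison of one center's main vs variant analysis.

    Keeps the union of significant diagnoses from either analysis with
    paired ORs, Spearman over the union, and the >=10-patient log-log plot
    filter.
    """
    merged = results_main.merge(
        results_variant, on="phecode", suffixes=("_main", "_variant"), how="inner"
    )
    sig = ((merged["p_adj_main"] < alpha) & merged["converged_main"]) | (
        (merged["p_adj_variant"] < alpha) & merged["converged_variant"]
    )
    out = merged.loc[
        sig,
        ["phecode", "or_value_main", "p_adj_main", "or_value_variant",
         "p_adj_variant", "n_rpl_with_main", "n_control_with_main"],
    ].reset_index(drop=True)
    out["plot_filter"] = (
        merged.loc[sig, ["n_rpl_with_main", "n_control_with_main"]].max(axis=1) >= 10
    ).to_numpy()
    converged = (merged.loc[sig, "converged_main"]
                 & merged.loc[sig, "converged_variant"]).to_numpy()
    if converged.sum() >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r, p = stats.spearmanr(
                out.loc[converged, "or_value_main"],
                out.loc[converged, "or_value_variant"],
            )
        out.attrs["spearman_r"], out.attrs["spearman_p"] = float(r), float(p)
    else:
        out.attrs["spearman_r"] = out.attrs["spearman_p"] = np.nan
    return out
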