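"""Next-pregnancy analysis: validated diagnoses vs outcome of the next pregnancy.

Among RPL patients with a recorded birth or loss at least 30 days after
their index date, each previously validated diagnosis is tested for its
association with loss (=1) vs birth (=0) of that next pregnancy, using the
same adjusted additive model (age smooth + race + ethnicity) and BH
correction. A diagnosis counts as present when any record of it is dated
strictly before the outcome date. Redaction follows the shared small-cell
policy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import (
    ModelSpec, apply_redaction, bh_adjust, classify_direction, fit_adjusted,
)
from .ehr_io import EhrBundle, PhecodeMap


def run_next_pregnancy(
    rpl_cohort: pd.DataFrame,
    outcomes: pd.DataFrame,
    bundle: EhrBundle,
    phecode_map: PhecodeMap,
    validated: pd.DataFrame,
    spec: ModelSpec | None = None,
) -> pd.DataFrame:
    """One adjusted fit per validated diagnosis against next-pregnancy loss.

    ``outcomes`` comes from :func:`rplphewas.cohort.find_next_outcome`;
    ``validated`` carries (phecode, direction) from the main analysis, used
    for the concordance flag (sign agreement between the next-pregnancy
    log-OR for loss and the main RPL direction).
    """
    spec = spec or ModelSpec()
    if validated.empty:
        raise ValueError("validated diagnosis set is empty")
    cases = rpl_cohort[rpl_cohort["group"] == "rpl"]
    design = outcomes.merge(
        cases[["person_id", "age_at_index", "race", "ethnicity",
               "n_visits_in_window"]],
        on="person_id", how="inner",
    )
    if len(design) != len(outcomes):
        raise ValueError("outcomes contain patients absent from the RPL cohort")
    y = (design["outcome"] == "loss").to_numpy(dtype=float)

    conds = bundle.conditions.merge(
        design[["person_id", "outcome_date"]], on="person_id", how="inner"
    )
    conds = conds[conds["start_date"] < conds["outcome_date"]]  # strictly before
    phe_rows = []
    for code in conds["concept_id"].unique():
        for ph in phecode_map.lookup(code):
            phe_rows.append((code, ph))
    code_to_phe = pd.DataFrame(phe_rows, columns=["concept_id", "phecode"])
    carried = conds.merge(code_to_phe, on="concept_id")[
        ["person_id", "phecode"]
    ].drop_duplicates()

    n_loss = int(y.sum())
    n_birth = int(len(y) - n_loss)
    results = []
    for _, row in validated.iterrows():
        phecode = row["phecode"]
        with_dx = set(carried.loc[carried["phecode"] == phecode, "person_id"])
        x_dx = design["person_id"].isin(with_dx).to_numpy(dtype=float)
        res = fit_adjusted(
            y, x_dx, design["age_at_index"], design["race"], design["ethnicity"],
            spec=spec, phecode=phecode,
        )
        res.n_rpl_with = int(x_dx[y == 1].sum())       # carriers with loss
        res.n_control_with = int(x_dx[y == 0].sum())   # carriers with birth
        res.n_rpl = n_loss
        res.n_control = n_birth
        results.append(res)

    df = pd.DataFrame([vars(r) for r in results])
    df["p_adj"] = bh_adjust(df["p"])
    df["direction"] = classify_direction(df, spec.alpha)
    df = apply_redaction(df, spec.redaction_threshold)
    df = df.rename(columns={
        "or_value": "or_for_loss",
        "n_rpl_with": "n_loss_with", "n_control_with": "n_birth_with",
        "n_rpl": "n_loss", "n_control": "n_birth",
    })
    main_dir = validated.set_index("phecode")["direction"]
    main_sign = df["phecode"].map(main_dir).map({"positive": 1.0, "negative": -1.0})
    with np.errstate(invalid="ignore"):
        next_sign = np.sign(np.log(df["or_for_loss"]))
    df["concordant_with_main"] = (main_sign * next_sign) > 0
    return df
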