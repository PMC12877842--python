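"""Per-diagnosis association models: crude and confounder-adjusted.

Crude associations are closed-form 2x2 odds ratios with Wald intervals on
the log scale. Adjusted associations come from an additive logistic model

    logit P(RPL = 1) = s(age) + race + ethnicity [+ visits] + beta * dx

where ``s`` is a cubic B-spline smooth of maternal age (default df = 4,
unpenalized; an optionally penalized fit via statsmodels GLMGam is
available), race/ethnicity enter as categoricals with the largest category
as reference and "Unknown" kept as an explicit level, and ``dx`` is the
binary presence of one candidate diagnosis. The reported odds ratio is
exp(beta) with a Wald 95% CI (z = 1.96) and a two-sided normal p-value.

p-values within one analysis family are Benjamini-Hochberg adjusted; any
result where a displayed group count falls below 10 is redacted to
directional bounds (">1", "<0.05"-style) without changing its significance
classification — mirroring small-cell disclosure practice for EHR data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from patsy import dmatrix
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

Z95 = 1.96
ALPHA = 0.05
SEPARATION_BETA = 15.0  # |log OR| beyond this is treated as diverging


@dataclass
class ModelSpec:
    """Adjusted-model configuration.

    ``age_df`` is the spline degrees of freedom (cubic basis). With
    ``age_linear`` the smooth is replaced by a single linear age term (used
    by the internal plain-logistic equivalence oracle). ``penalized``
    switches to a penalized smooth fitted with statsmodels GLMGam, with
    ``penalty_alpha`` chosen by generalized cross-validation when ``gcv`` is
    set.
    """

    age_df: int = 4
    age_linear: bool = False
    penalized: bool = False
    penalty_alpha: float = 1.0
    gcv: bool = False
    include_visits: bool = False
    redaction_threshold: int = 10
    alpha: float = ALPHA


@dataclass
class AssociationResult:
    phecode: str
    beta: float
    se: float
    or_value: float
    ci_low: float
    ci_high: float
    p: float
    p_adj: float = np.nan
    n_rpl_with: int = 0
    n_control_with: int = 0
    n_rpl: int = 0
    n_control: int = 0
    converged: bool = True
    redacted: bool = False
    direction: str = "null"


def crude_or(n11: float, n10: float, n01: float, n00: float):
    """Closed-form 2x2 odds ratio (exposed/unexposed x case/control).

    Returns (or_value, (ci_low, ci_high), p). Any zero cell triggers the
    Haldane-Anscombe 0.5 correction and the result is flagged non-converged
    via ``or_value`` being derived from corrected counts; an all-zero margin
    returns NaNs.
    """
    cells = np.array([n11, n10, n01, n00], dtype=float)
    if (cells < 0).any():
        raise ValueError("2x2 counts must be nonnegative")
    converged = not (cells == 0).any()
    if (cells[[0, 1]].sum() == 0 or cells[[2, 3]].sum() == 0
            or cells[[0, 2]].sum() == 0 or cells[[1, 3]].sum() == 0):
        return np.nan, (np.nan, np.nan), np.nan, False
    if not converged:
        cells = cells + 0.5
    a, b, c, d = cells
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    p = 2 * stats.norm.sf(abs(log_or) / se)
    ci = (np.exp(log_or - Z95 * se), np.exp(log_or + Z95 * se))
    return float(np.exp(log_or)), ci, float(p), converged


def _age_basis(age: np.ndarray, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    if spec.age_linear:
        return age.reshape(-1, 1), ["age"]
    basis = np.asarray(
        dmatrix(
            f"bs(x, df={spec.age_df}, degree=3, include_intercept=False) - 1",
            {"x": age},
            return_type="matrix",
        )
    )
    return basis, [f"age_s{i + 1}" for i in range(basis.shape[1])]


def _dummies(values: pd.Series, prefix: str) -> tuple[np.ndarray, list[str]]:
    # reference level = largest category (stabilizes the fit)
    values = pd.Series(np.asarray(values, dtype=object))
    counts = values.value_counts()
    ref = counts.index[0]
    levels = [lv for lv in counts.index if lv != ref]
    cols = np.column_stack([(values == lv).astype(float) for lv in levels]) if levels \
        else np.empty((len(values), 0))
    return cols, [f"{prefix}[{lv}]" for lv in levels]


def build_design(
    age, race, ethnicity, visits=None, spec: ModelSpec | None = None,
    drop_collinear: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """Base design matrix (everything except the diagnosis term).

    A rank-deficient design raises, naming the collinear columns. With
    ``drop_collinear`` (the sweep path, where sparse strata can make rare
    category dummies linearly dependent) the dependent columns identified by
    pivoted QR are dropped instead — the model span is unchanged.
    """
    spec = spec or ModelSpec()
    age = np.asarray(age, dtype=float)
    parts = [np.ones((len(age), 1))]
    names = ["intercept"]
    b, bn = _age_basis(age, spec)
    parts.append(b)
    names += bn
    for values, prefix in ((race, "race"), (ethnicity, "ethnicity")):
        cols, cn = _dummies(values, prefix)
        parts.append(cols)
        names += cn
    if spec.include_visits:
        if visits is None:
            raise ValueError("include_visits=True but no visits supplied")
        parts.append(np.asarray(visits, dtype=float).reshape(-1, 1))
        names.append("n_visits")
    X = np.hstack(parts)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        if not drop_collinear:
            collinear = _collinear_columns(X, names)
            raise ValueError(f"singular design; collinear columns: {collinear}")
        from scipy.linalg import qr

        _, _, pivot = qr(X, mode="economic", pivoting=True)
        drop = sorted(pivot[rank:])
        keep = [j for j in range(X.shape[1]) if j not in set(drop)]
        X = X[:, keep]
        names = [names[j] for j in keep]
    return X, names


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(X):
            bad.append(names[j])
    return bad or names


def _fit_logistic(X: np.ndarray, y: np.ndarray):
    """IRLS logistic fit; returns (params, bse, converged)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
        except Exception:
            return None, None, False
    converged = bool(getattr(res, "converged", True))
    return np.asarray(res.params), np.asarray(res.bse), converged


def _result_from_beta(phecode, beta, se, converged) -> AssociationResult:
    if beta is None or not np.isfinite(beta) or not np.isfinite(se) or se == 0:
        return AssociationResult(
            phecode, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, converged=False
        )
    diverged = abs(beta) > SEPARATION_BETA or se > 50
    p = float(2 * stats.norm.sf(abs(beta) / se))
    with np.errstate(over="ignore"):
        res = AssociationResult(
            phecode=phecode,
            beta=float(beta),
            se=float(se),
            or_value=float(np.exp(beta)),
            ci_low=float(np.exp(beta - Z95 * se)),
            ci_high=float(np.exp(beta + Z95 * se)),
            p=p,
            converged=converged and not diverged,
        )
    return res


def fit_adjusted(
    y, x_dx, age, race, ethnicity, visits=None, spec: ModelSpec | None = None,
    phecode: str = "",
) -> AssociationResult:
    """Fit the additive model for one diagnosis and return its Wald summary."""
    spec = spec or ModelSpec()
    y = np.asarray(y, dtype=float)
    x_dx = np.asarray(x_dx, dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one case and one control")
    if spec.penalized and not spec.age_linear:
        return _fit_penalized(y, x_dx, age, race, ethnicity, visits, spec, phecode)
    X0, _ = build_design(age, race, ethnicity, visits, spec)
    return _fit_with_dx(X0, y, x_dx, phecode)


def _fit_with_dx(X0: np.ndarray, y: np.ndarray, x_dx: np.ndarray, phecode: str):
    if x_dx.std() == 0:
        return AssociationResult(
            phecode, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, converged=False
        )
    X = np.hstack([X0, x_dx.reshape(-1, 1)])
    params, bse, converged = _fit_logistic(X, y)
    if params is None:
        return AssociationResult(
            phecode, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, converged=False
        )
    return _result_from_beta(phecode, params[-1], bse[-1], converged)


def _fit_penalized(y, x_dx, age, race, ethnicity, visits, spec, phecode):
    from statsmodels.gam.api import BSplines, GLMGam

    age = np.asarray(age, dtype=float).reshape(-1, 1)
    smoother = BSplines(age, df=[max(spec.age_df + 3, 5)], degree=[3])
    parts = [np.ones((len(y), 1))]
    names = ["intercept"]
    for values, prefix in ((race, "race"), (ethnicity, "ethnicity")):
        cols, cn = _dummies(values, prefix)
        parts.append(cols)
        names += cn
    if spec.include_visits:
        parts.append(np.asarray(visits, dtype=float).reshape(-1, 1))
        names.append("n_visits")
    parts.append(np.asarray(x_dx, dtype=float).reshape(-1, 1))
    exog = np.hstack(parts)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = GLMGam(
            y, exog=exog, smoother=smoother, alpha=[spec.penalty_alpha],
            family=sm.families.Binomial(),
        )
        if spec.gcv:
            try:
                alpha_opt = model.select_penweight()[0]
                model = GLMGam(
                    y, exog=exog, smoother=smoother, alpha=alpha_opt,
                    family=sm.families.Binomial(),
                )
            except Exception:
                pass
        try:
            res = model.fit()
        except Exception:
            return AssociationResult(
                phecode, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, converged=False
            )
    j = exog.shape[1] - 1  # dx column
    return _result_from_beta(
        phecode, res.params[j], res.bse[j], bool(getattr(res, "converged", True))
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving.

    NaNs (e.g., non-converged fits) pass through as NaN and are excluded
    from the family size.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def run_phewas(
    matrix, cohort: pd.DataFrame | None = None, spec: ModelSpec | None = None
) -> pd.DataFrame:
    """One adjusted fit per candidate diagnosis, BH within the family.

    Per-diagnosis non-convergence is carried as a flag, never aborts the
    sweep. Returns a DataFrame of :class:`AssociationResult` fields plus
    ``phecode_string``/``category`` metadata and redaction display columns.
    """
    spec = spec or ModelSpec()
    patients = cohort if cohort is not None else matrix.patients
    patients = patients.set_index("person_id").loc[matrix.presence.index]
    y = (patients["group"] == "rpl").to_numpy(dtype=float)
    visits = patients["n_visits_in_window"] if "n_visits_in_window" in patients else None
    X0, _ = build_design(
        patients["age_at_index"], patients["race"], patients["ethnicity"],
        visits, spec, drop_collinear=True,
    )
    n_rpl = int(y.sum())
    n_control = int(len(y) - n_rpl)

    results = []
    counts = matrix.diagnoses.set_index("phecode")
    for phecode in matrix.phecodes:
        x_dx = matrix.presence[phecode].to_numpy(dtype=float)
        if spec.penalized:
            res = fit_adjusted(
                y, x_dx, patients["age_at_index"], patients["race"],
                patients["ethnicity"], visits, spec, phecode,
            )
        else:
            res = _fit_with_dx(X0, y, x_dx, phecode)
        res.n_rpl_with = int(counts.loc[phecode, "n_rpl_with"])
        res.n_control_with = int(counts.loc[phecode, "n_control_with"])
        res.n_rpl = n_rpl
        res.n_control = n_control
        results.append(res)

    df = pd.DataFrame([vars(r) for r in results])
    df["p_adj"] = bh_adjust(df["p"])
    df["direction"] = classify_direction(df, spec.alpha)
    df = apply_redaction(df, spec.redaction_threshold)
    meta = matrix.diagnoses.set_index("phecode")
    df.insert(1, "phecode_string", df["phecode"].map(meta["phecode_string"]))
    df.insert(2, "category", df["phecode"].map(meta["category"]))
    return df


def phewas_frame(frame: pd.DataFrame, spec: ModelSpec | None = None) -> pd.DataFrame:
    """PheWAS sweep over the ``dx_*`` columns of an analysis-ready frame.

    ``frame`` follows the :func:`rplphewas.synth.simulate_case_control`
    layout (``y``, ``age``, ``race``, ``ethnicity``, ``visits``, ``dx_*``);
    this is the fast path for calibration experiments that fit thousands of
    replicates without materializing EHR records.
    """
    spec = spec or ModelSpec()
    y = frame["y"].to_numpy(dtype=float)
    visits = frame["visits"] if "visits" in frame else None
    X0, _ = build_design(frame["age"], frame["race"], frame["ethnicity"], visits, spec,
                         drop_collinear=True)
    n_rpl = int(y.sum())
    n_control = int(len(y) - n_rpl)
    results = []
    for col in [c for c in frame.columns if c.startswith("dx_")]:
        x_dx = frame[col].to_numpy(dtype=float)
        res = _fit_with_dx(X0, y, x_dx, col[3:])
        res.n_rpl_with = int(x_dx[y == 1].sum())
        res.n_control_with = int(x_dx[y == 0].sum())
        res.n_rpl, res.n_control = n_rpl, n_control
        results.append(res)
    df = pd.DataFrame([vars(r) for r in results])
    df["p_adj"] = bh_adjust(df["p"])
    df["direction"] = classify_direction(df, spec.alpha)
    return apply_redaction(df, spec.redaction_threshold)


def classify_direction(df: pd.DataFrame, alpha: float = ALPHA) -> pd.Series:
    sig = (df["p_adj"] < alpha) & df["converged"]
    return pd.Series(
        np.where(sig & (df["or_value"] > 1), "positive",
                 np.where(sig & (df["or_value"] < 1), "negative", "null")),
        index=df.index,
    )


def apply_redaction(df: pd.DataFrame, threshold: int = 10) -> pd.DataFrame:
    """Flag small-cell results and attach directional display bounds.

    A result is redacted when any of the four displayed counts (carriers and
    non-carriers per group) falls below ``threshold``. Numeric fields are
    left intact for downstream classification; :func:`format_for_export`
    masks them in written tables.
    """
    df = df.copy()
    cell_min = np.minimum.reduce(
        [
            df["n_rpl_with"].to_numpy(),
            df["n_control_with"].to_numpy(),
            (df["n_rpl"] - df["n_rpl_with"]).to_numpy(),
            (df["n_control"] - df["n_control_with"]).to_numpy(),
        ]
    )
    df["redacted"] = cell_min < threshold
    or_bound = np.where(df["or_value"] > 1, ">1", "<1")
    p_bound = np.where(df["p_adj"] < ALPHA, "<0.05", ">=0.05")
    df["or_display"] = np.where(
        df["redacted"], or_bound, df["or_value"].round(4).astype(str)
    )
    df["p_display"] = np.where(
        df["redacted"], p_bound, df["p"].map(lambda v: f"{v:.3g}")
    )
    return df


def format_for_export(df: pd.DataFrame) -> pd.DataFrame:
    """Mask exact estimates, intervals, p-values, and counts on redacted rows."""
    out = df.copy()
    numeric = ["beta", "se", "or_value", "ci_low", "ci_high", "p", "p_adj",
               "n_rpl_with", "n_control_with"]
    out.loc[out["redacted"], numeric] = np.nan
    return out


def plot_table(df: pd.DataFrame) -> pd.DataFrame:
    """Volcano/manhattan-ready table: log10 OR and -log10 adjusted p."""
    out = df[["phecode", "phecode_string", "category"]].copy()
    with np.errstate(divide="ignore"):
        out["log10_or"] = np.log10(df["or_value"])
        out["neg_log10_p_adj"] = -np.log10(df["p_adj"])
    out["direction"] = df["direction"]
    return out
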