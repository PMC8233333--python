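"""Survival and correlation statistics for dichotomized biomarker groups.

Provides the statistical toolkit applied to high/low biomarker groups:
Kaplan-Meier curves, the two-group log-rank test with an O/E
(Mantel-Haenszel) hazard ratio, multivariate Cox proportional hazards with
categorical covariate coding (age category, T stage, nodal status),
a likelihood-ratio test for a group x modifier interaction, Spearman
correlation matrices with Benjamini-Hochberg adjustment, and the robust
z-score transform used for heatmap display.

Survival times are in months. Kaplan-Meier and Cox fits delegate to
lifelines (Efron tie handling); the log-rank statistic and O/E hazard ratio
are computed directly from the risk tables because the O/E ratio is not
exposed by library fitters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats
from scipy.stats import median_abs_deviation
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "kaplan_meier",
    "logrank_test",
    "cox_multivariate",
    "interaction_lrt",
    "spearman_bh",
    "robust_zscore",
    "AGE_CATEGORIES",
    "T_STAGES",
    "N_LEVELS",
]

AGE_CATEGORIES = ["<40", "40-49", "50-59", ">60"]
T_STAGES = [1, 2, 3, 4]
N_LEVELS = ["negative", "positive"]

_Z975 = 1.959963984540054


@dataclass
class TestResult:
    """A two-group comparison: hazard ratio (high vs low), CI, p-value."""

    statistic: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_per_group: dict = field(default_factory=dict)
    method: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.hazard_ratio) and self.hazard_ratio <= 0:
            raise ValueError("hazard ratio must be positive")


def _check_records(records: pd.DataFrame) -> None:
    for col in ("time", "event", "group"):
        if col not in records:
            raise ValueError(f"records must contain a {col!r} column")
    if (records["time"] <= 0).any():
        raise ValueError("survival times must be positive")


def kaplan_meier(records: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival estimate per group.

    Returns a long DataFrame (group, time, survival); each group's curve
    starts at S(0) = 1 and is a right-continuous non-increasing step
    function.
    """
    _check_records(records)
    frames = []
    for grp, sub in records.groupby("group", sort=True):
        km = KaplanMeierFitter()
        km.fit(sub["time"], sub["event"].astype(bool))
        sf = km.survival_function_
        frames.append(
            pd.DataFrame(
                {
                    "group": grp,
                    "time": sf.index.to_numpy(dtype=float),
                    "survival": sf.iloc[:, 0].to_numpy(dtype=float),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _risk_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per event time: at-risk and event counts, overall and in group high."""
    t = records["time"].to_numpy(dtype=float)
    e = records["event"].to_numpy(dtype=bool)
    is_high = records["group"].to_numpy() == "high"
    event_times = np.unique(t[e])
    rows = []
    for et in event_times:
        at_risk = t >= et
        died = e & (t == et)
        rows.append(
            {
                "time": et,
                "n": int(at_risk.sum()),
                "n_high": int((at_risk & is_high).sum()),
                "d": int(died.sum()),
                "d_high": int((died & is_high).sum()),
            }
        )
    return pd.DataFrame(rows)


def logrank_test(records: pd.DataFrame) -> TestResult:
    """Two-group log-rank test with Mantel-Haenszel O/E hazard ratio.

    At each distinct event time the observed high-group events are compared
    with their hypergeometric expectation given the at-risk sets; the
    chi-square statistic is (O - E)^2 / V with 1 df. The hazard ratio is
    (O_high / E_high) / (O_low / E_low) with a log-scale CI from
    sqrt(1/E_high + 1/E_low).
    """
    _check_records(records)
    groups = set(records["group"])
    if groups != {"high", "low"}:
        raise ValueError(f"need both 'high' and 'low' groups, got {sorted(groups)}")
    if records["event"].sum() == 0:
        raise ValueError("need at least one event")

    rt = _risk_table(records)
    e_high = (rt["d"] * rt["n_high"] / rt["n"]).sum()
    o_high = rt["d_high"].sum()
    o_low = rt["d"].sum() - o_high
    e_low = rt["d"].sum() - e_high
    with np.errstate(invalid="ignore", divide="ignore"):
        v = (
            rt["d"]
            * (rt["n_high"] / rt["n"])
            * (1 - rt["n_high"] / rt["n"])
            * (rt["n"] - rt["d"])
            / (rt["n"] - 1)
        )
    v = float(np.nansum(v.to_numpy()))
    statistic = (o_high - e_high) ** 2 / v if v > 0 else 0.0
    p = float(stats.chi2.sf(statistic, df=1)) if v > 0 else 1.0

    if o_high > 0 and o_low > 0:
        hr = (o_high / e_high) / (o_low / e_low)
        se = np.sqrt(1.0 / e_high + 1.0 / e_low)
        ci = (np.exp(np.log(hr) - _Z975 * se), np.exp(np.log(hr) + _Z975 * se))
    else:
        hr, ci = float("nan"), (float("nan"), float("nan"))
    n_per = records["group"].value_counts().to_dict()
    return TestResult(
        statistic=float(statistic),
        hazard_ratio=float(hr),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=p,
        n_per_group=n_per,
        method="logrank",
    )


def _design_matrix(records: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Dummy-code the group and categorical covariates against first levels."""
    df = pd.DataFrame(index=records.index)
    df["group_high"] = (records["group"] == "high").astype(float)
    levels = {"age_category": AGE_CATEGORIES, "t_stage": T_STAGES, "n_status": N_LEVELS}
    for cov in covariates:
        col = records[cov]
        if cov in levels:
            cats = levels[cov]
            bad = set(col) - set(cats)
            if bad:
                raise ValueError(f"{cov} contains unknown levels {sorted(map(str, bad))}")
            cat = pd.Categorical(col, categories=cats)
            dummies = pd.get_dummies(cat, prefix=cov, drop_first=True, dtype=float)
            dummies.index = records.index
            df = pd.concat([df, dummies], axis=1)
        elif pd.api.types.is_numeric_dtype(col):
            df[cov] = col.astype(float)
        else:
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            df = pd.concat([df, dummies], axis=1)
    # drop dummy columns with no variation (level absent from the data)
    keep = [c for c in df.columns if df[c].nunique() > 1 or c == "group_high"]
    if df["group_high"].nunique() < 2:
        raise ValueError("group indicator has no variation")
    return df[keep]


def _fit_cox(design: pd.DataFrame, records: pd.DataFrame) -> CoxPHFitter:
    data = design.copy()
    data["time"] = records["time"].to_numpy(dtype=float)
    data["event"] = records["event"].to_numpy(dtype=float)
    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col="time", event_col="event")
    except ConvergenceError as err:
        raise RuntimeError(f"Cox model failed to converge: {err}") from err
    return cph


def cox_multivariate(
    records: pd.DataFrame,
    covariates: list[str] | None = None,
) -> tuple[TestResult, pd.DataFrame]:
    """Cox PH fit of the group effect adjusted for clinical covariates.

    Covariates default to age category, T stage and nodal status when those
    columns are present; categorical covariates are dummy-coded against
    their first level and ties are handled by Efron's method. Returns the
    adjusted group TestResult plus a table of per-covariate hazard ratios.
    """
    _check_records(records)
    if covariates is None:
        covariates = [
            c for c in ("age_category", "t_stage", "n_status") if c in records.columns
        ]
    design = _design_matrix(records, covariates)
    cph = _fit_cox(design, records)

    summary = cph.summary
    grp = summary.loc["group_high"]
    result = TestResult(
        statistic=float(grp["z"]),
        hazard_ratio=float(grp["exp(coef)"]),
        ci_low=float(grp["exp(coef) lower 95%"]),
        ci_high=float(grp["exp(coef) upper 95%"]),
        p_value=float(grp["p"]),
        n_per_group=records["group"].value_counts().to_dict(),
        method="cox",
    )
    per_cov = summary.loc[
        summary.index != "group_high",
        ["exp(coef)", "exp(coef) lower 95%", "exp(coef) upper 95%", "p"],
    ].rename(
        columns={
            "exp(coef)": "hazard_ratio",
            "exp(coef) lower 95%": "ci_low",
            "exp(coef) upper 95%": "ci_high",
            "p": "p_value",
        }
    )
    return result, per_cov


def interaction_lrt(
    records: pd.DataFrame,
    modifier: str,
    covariates: list[str] | None = None,
    include_interaction: bool = True,
) -> dict:
    """Likelihood-ratio test for a group x modifier interaction.

    Fits Cox models with and without the interaction term(s) and compares
    2 * (loglik_full - loglik_reduced) against a chi-square with one df per
    interaction parameter. Both modifier levels must contain both groups.
    With ``include_interaction=False`` the full model equals the reduced
    one: the statistic is 0 with p = 1 (degenerate comparison).
    """
    _check_records(records)
    if modifier not in records:
        raise ValueError(f"records lack the modifier column {modifier!r}")
    crosstab = pd.crosstab(records[modifier], records["group"])
    if (crosstab == 0).any().any() or crosstab.shape != (2, 2):
        raise ValueError("both modifier levels must contain both groups")
    covariates = covariates or []

    design = _design_matrix(records, covariates)
    mod_dummy = pd.get_dummies(
        records[modifier], prefix=modifier, drop_first=True, dtype=float
    )
    mod_dummy.index = records.index
    reduced = pd.concat([design, mod_dummy], axis=1)
    full = reduced.copy()
    inter_cols = []
    if include_interaction:
        for c in mod_dummy.columns:
            name = f"group_high:{c}"
            full[name] = full["group_high"] * full[c]
            inter_cols.append(name)

    ll_reduced = _fit_cox(reduced, records).log_likelihood_
    ll_full = _fit_cox(full, records).log_likelihood_
    statistic = 2.0 * (ll_full - ll_reduced)
    if statistic < -1e-6:
        raise RuntimeError(
            f"nested log-likelihood ordering violated: full {ll_full} < reduced {ll_reduced}"
        )
    statistic = max(statistic, 0.0)
    df = len(inter_cols)
    p = float(stats.chi2.sf(statistic, df=df)) if df > 0 else 1.0
    if df == 0:
        statistic = 0.0
    return {"statistic": float(statistic), "df": df, "p_value": p}


def spearman_bh(data: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlations with BH-adjusted p-values.

    ``data`` is samples x variables. Ties get average ranks. The BH
    correction is applied over the upper-triangle p-values only; constant
    variables yield NaN ("undefined") entries that are excluded from the
    adjustment. Diagonals are rho 1 / p NaN.
    """
    if data.shape[0] < 3:
        raise ValueError("need >= 3 paired observations")
    cols = list(data.columns)
    k = len(cols)
    rho = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    praw = pd.DataFrame(np.full((k, k), np.nan), index=cols, columns=cols)
    for i in range(k):
        for j in range(i + 1, k):
            x = data.iloc[:, i].to_numpy(dtype=float)
            y = data.iloc[:, j].to_numpy(dtype=float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                rho.iloc[i, j] = rho.iloc[j, i] = np.nan
                continue
            r, p = stats.spearmanr(x, y)
            rho.iloc[i, j] = rho.iloc[j, i] = r
            praw.iloc[i, j] = praw.iloc[j, i] = p
    iu = np.triu_indices(k, 1)
    pvals = praw.to_numpy()[iu]
    padj = pd.DataFrame(np.full((k, k), np.nan), index=cols, columns=cols)
    mask = np.isfinite(pvals)
    if mask.any():
        adj = np.full(len(pvals), np.nan)
        adj[mask] = multipletests(pvals[mask], method="fdr_bh")[1]
        out = padj.to_numpy()
        out[iu] = adj
        out[(iu[1], iu[0])] = adj
        padj = pd.DataFrame(out, index=cols, columns=cols)
    return rho, padj


def robust_zscore(matrix, axis: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Robust z-score transform: (x - median) / (1.4826 * MAD).

    Applied along ``axis`` (1 = within rows). Slices with MAD 0 are
    flagged and returned as zeros. Returns (transformed, flagged) where
    ``flagged`` marks the degenerate rows/columns.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim == 1:
        x = x[None, :] if axis == 1 else x[:, None]
    if x.shape[axis] < 2:
        raise ValueError("need >= 2 values along the transform axis")
    med = np.median(x, axis=axis, keepdims=True)
    mad = median_abs_deviation(x, axis=axis, scale="normal")  # 1.4826 * raw MAD
    mad_k = np.expand_dims(mad, axis=axis)
    flagged = mad == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - med) / mad_k
    z = np.where(np.expand_dims(flagged, axis=axis), 0.0, z)
    return np.asarray(z), flagged
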