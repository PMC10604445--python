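"""Sex-stratified statistical analysis of a muscle-composition cohort.

Implements the analysis stage applied to a patient table: Kjaer FI grouping
(<10 / 10-50 / >=50 %, collapsed at 50%), normality-gated two-group
comparisons (Student t when Shapiro-Wilk accepts normality in both groups,
Mann-Whitney U otherwise), full Spearman correlation matrices between
posterior-paraspinal and psoas measures per sex, and an ordinary
least-squares regression of FI_Psoas on FI_PPM, age, BMI, sex and race with
the complete diagnostic report (b, 95% CI, SE, standardized Beta, t, p, VIF,
adjusted R^2, Durbin-Watson, overall F).

No multiple-testing adjustment is applied anywhere: every p-value is
reported raw, and significance statements use the unadjusted 0.05 level.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.stattools import durbin_watson

__all__ = [
    "FiGroup",
    "GroupComparisonResult",
    "RegressionReport",
    "classify_fi_group",
    "normality_gate",
    "compare_groups",
    "spearman_matrix",
    "fit_regression",
    "analyze_cohort",
    "write_reports",
]

MEASURES = ("CSA", "fCSA", "FAT", "FI")
MUSCLE_SUFFIXES = ("PPM", "Psoas")
DEFAULT_PREDICTORS = ("FI_PPM", "age", "BMI", "sex_female", "race_other")


@dataclass(frozen=True)
class FiGroup:
    """Three-level Kjaer group and its collapsed (<50 vs >=50) form."""

    level: str  # low / medium / high
    collapsed: str  # low_to_moderate / high


def classify_fi_group(fi: float) -> FiGroup:
    """Kjaer fat-infiltration grouping.

    low: FI < 10; medium: 10 <= FI < 50; high: FI >= 50. The collapsed rule
    merges low and medium into "low_to_moderate".
    """
    if not 0.0 <= fi <= 100.0:
        raise ValueError(f"FI must be in [0, 100], got {fi}")
    if fi < 10.0:
        level = "low"
    elif fi < 50.0:
        level = "medium"
    else:
        level = "high"
    return FiGroup(level=level, collapsed="high" if level == "high" else "low_to_moderate")


def normality_gate(
    group_a: np.ndarray, group_b: np.ndarray, alpha: float = 0.05
) -> tuple[str, tuple[float, float]]:
    """Choose the two-group test from per-group Shapiro-Wilk normality.

    Returns ("t" | "mannwhitney", (shapiro_p_a, shapiro_p_b)); the t-test is
    chosen only when both groups pass the normality test at ``alpha``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    for name, g in (("first", a), ("second", b)):
        if g.size < 3:
            raise ValueError(
                f"{name} group has {g.size} values; Shapiro-Wilk needs at least 3"
            )
    p_a = float(sps.shapiro(a).pvalue)
    p_b = float(sps.shapiro(b).pvalue)
    choice = "t" if (p_a >= alpha and p_b >= alpha) else "mannwhitney"
    return choice, (p_a, p_b)


@dataclass(frozen=True)
class GroupComparisonResult:
    variable: str
    stratum: str
    test: str  # "t" or "mannwhitney"
    statistic: float
    p_value: float
    n_low: int
    n_high: int
    summary_low: str
    summary_high: str
    shapiro_p: tuple[float, float]


def _summarize(values: np.ndarray, parametric: bool) -> str:
    if parametric:
        return f"{np.mean(values):.1f} ± {np.std(values, ddof=1):.1f}"
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return f"{med:.2f} [{q1:.2f};{q3:.2f}]"


def compare_groups(
    df: pd.DataFrame,
    variable: str,
    sex: str,
    group_column: str = "FI_group",
    alpha: float = 0.05,
) -> GroupComparisonResult:
    """Compare ``variable`` between collapsed FI_PPM groups within one sex.

    The Shapiro-Wilk gate picks Student's t (equal-variance, the convention
    paired with this gate) or the Mann-Whitney U test; summaries follow the
    test (mean +/- SD for t, median [IQR] for Mann-Whitney).
    """
    stratum = df[df["sex"] == sex]
    low = stratum.loc[stratum[group_column] == "low_to_moderate", variable].to_numpy()
    high = stratum.loc[stratum[group_column] == "high", variable].to_numpy()
    for name, g in (("low_to_moderate", low), ("high", high)):
        if g.size == 0:
            raise ValueError(f"empty {name} group in {sex} stratum for {variable}")
    choice, shapiro_p = normality_gate(low, high, alpha=alpha)
    if choice == "t":
        res = sps.ttest_ind(low, high)
    else:
        res = sps.mannwhitneyu(low, high, alternative="two-sided")
    parametric = choice == "t"
    return GroupComparisonResult(
        variable=variable,
        stratum=sex,
        test=choice,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_low=int(low.size),
        n_high=int(high.size),
        summary_low=_summarize(low, parametric),
        summary_high=_summarize(high, parametric),
        shapiro_p=shapiro_p,
    )


def spearman_matrix(df: pd.DataFrame, sex: str) -> pd.DataFrame:
    """Spearman rank correlations between all PPM and psoas measures, one sex.

    Returns a tidy frame with one row per (psoas measure, PPM measure) pair:
    rho (mid-rank ties), p (t-approximation), n, and a ``degenerate`` flag
    for constant columns (rho reported as NaN there).
    """
    stratum = df[df["sex"] == sex]
    if len(stratum) < 4:
        raise ValueError(f"need at least 4 records in the {sex} stratum")
    rows = []
    for pso in MEASURES:
        for ppm in MEASURES:
            x = stratum[f"{ppm}_PPM"].to_numpy(dtype=float)
            y = stratum[f"{pso}_Psoas"].to_numpy(dtype=float)
            degenerate = np.ptp(x) == 0 or np.ptp(y) == 0
            if degenerate:
                rho, p = np.nan, np.nan
            else:
                rho, p = sps.spearmanr(x, y)
            rows.append(
                {
                    "sex": sex,
                    "psoas_measure": pso,
                    "ppm_measure": ppm,
                    "rho": rho,
                    "p": p,
                    "n": len(stratum),
                    "degenerate": degenerate,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RegressionReport:
    """Full OLS report: per-predictor table plus model diagnostics."""

    table: pd.DataFrame  # index: const + predictors; b, ci_low, ci_high, se, beta, t, p, vif
    r_squared: float
    adj_r_squared: float
    f_pvalue: float
    durbin_watson: float
    n: int
    dependent: str

    def __post_init__(self) -> None:
        if not self.adj_r_squared <= self.r_squared + 1e-12:
            raise ValueError("adjusted R^2 cannot exceed R^2")


def _design_frame(df: pd.DataFrame, predictors: tuple[str, ...]) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    for name in predictors:
        if name == "sex_female":
            X[name] = (df["sex"] == "female").astype(float)
        else:
            X[name] = df[name].astype(float)
    return X


def fit_regression(
    df: pd.DataFrame,
    dependent: str = "FI_Psoas",
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
) -> RegressionReport:
    """OLS of ``dependent`` on ``predictors`` with the full diagnostic report.

    Standardized Beta is b * sd(x)/sd(y) with n-1 sample SDs; VIF_j is
    1/(1 - R^2_j) from regressing predictor j on the remaining predictors;
    the Durbin-Watson statistic runs over residuals in table row order.
    """
    y = df[dependent].astype(float)
    X = _design_frame(df, predictors)
    if len(df) <= len(predictors) + 1:
        raise ValueError("not enough records for the number of predictors")
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant predictor column(s): {constant}")
    Xc = sm.add_constant(X)
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        pairs = corr.stack()[lambda s: s > 1 - 1e-10].index.tolist()
        raise ValueError(f"rank-deficient design; collinear columns: {pairs}")

    fit = sm.OLS(y, Xc).fit()
    ci = fit.conf_int(alpha=0.05)
    sd_y = y.std(ddof=1)
    rows = []
    for name in Xc.columns:
        beta = np.nan
        vif = np.nan
        if name != "const":
            beta = fit.params[name] * X[name].std(ddof=1) / sd_y
            others = [c for c in X.columns if c != name]
            aux = sm.OLS(X[name], sm.add_constant(X[others])).fit()
            vif = 1.0 / (1.0 - aux.rsquared)
        rows.append(
            {
                "predictor": name,
                "b": fit.params[name],
                "ci_low": ci.loc[name, 0],
                "ci_high": ci.loc[name, 1],
                "se": fit.bse[name],
                "beta": beta,
                "t": fit.tvalues[name],
                "p": fit.pvalues[name],
                "vif": vif,
            }
        )
    table = pd.DataFrame(rows).set_index("predictor")
    return RegressionReport(
        table=table,
        r_squared=float(fit.rsquared),
        adj_r_squared=float(fit.rsquared_adj),
        f_pvalue=float(fit.f_pvalue),
        durbin_watson=float(durbin_watson(fit.resid.to_numpy())),
        n=int(len(df)),
        dependent=dependent,
    )


# ---------------------------------------------------------------------------
# Whole-cohort report bundle
# ---------------------------------------------------------------------------


def _demographics(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for label, sub in (("all", df), ("female", df[df.sex == "female"]), ("male", df[df.sex == "male"])):
        q_age = np.percentile(sub["age"], [25, 50, 75])
        q_bmi = np.percentile(sub["BMI"], [25, 50, 75])
        row = {
            "stratum": label,
            "n": len(sub),
            "age_median": q_age[1],
            "age_q1": q_age[0],
            "age_q3": q_age[2],
            "bmi_median": q_bmi[1],
            "bmi_q1": q_bmi[0],
            "bmi_q3": q_bmi[2],
        }
        for race, count in sub["race"].value_counts().items():
            row[f"race_{race.replace(' ', '_')}"] = count
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_cohort(df: pd.DataFrame, alpha: float = 0.05) -> dict[str, object]:
    """Run the full analysis stage on a patient table.

    Returns a dict with: ``demographics``; ``group_comparison`` (every
    muscle measure vs collapsed FI_PPM group, per sex); ``correlations``
    (Spearman matrices per sex); ``regression`` (a RegressionReport);
    ``lordosis`` (LL vs collapsed group per sex); ``test_log`` (every
    gate decision with its Shapiro-Wilk p-values).
    """
    if "FI_group" not in df.columns:
        df = df.copy()
        groups = df["FI_PPM"].map(classify_fi_group)
        df["FI_group"] = [g.collapsed for g in groups]

    comparisons = []
    log_rows = []
    for sex in ("female", "male"):
        for muscle in MUSCLE_SUFFIXES:
            for measure in MEASURES:
                var = f"{measure}_{muscle}"
                res = compare_groups(df, var, sex, alpha=alpha)
                comparisons.append(res)
                log_rows.append(
                    {
                        "variable": var,
                        "sex": sex,
                        "test": res.test,
                        "shapiro_p_low": res.shapiro_p[0],
                        "shapiro_p_high": res.shapiro_p[1],
                    }
                )
    comparison_df = pd.DataFrame(
        {
            "sex": r.stratum,
            "variable": r.variable,
            "low_to_moderate": r.summary_low,
            "high": r.summary_high,
            "n_low": r.n_low,
            "n_high": r.n_high,
            "test": r.test,
            "statistic": r.statistic,
            "p": r.p_value,
        }
        for r in comparisons
    )

    corr = pd.concat(
        [spearman_matrix(df, "female"), spearman_matrix(df, "male")],
        ignore_index=True,
    )

    lordosis_rows = []
    for sex in ("female", "male"):
        res = compare_groups(df, "LL", sex, alpha=alpha)
        lordosis_rows.append(res)
        log_rows.append(
            {
                "variable": "LL",
                "sex": sex,
                "test": res.test,
                "shapiro_p_low": res.shapiro_p[0],
                "shapiro_p_high": res.shapiro_p[1],
            }
        )
    lordosis_df = pd.DataFrame(
        {
            "sex": r.stratum,
            "low_to_moderate": r.summary_low,
            "high": r.summary_high,
            "test": r.test,
            "statistic": r.statistic,
            "p": r.p_value,
        }
        for r in lordosis_rows
    )

    return {
        "demographics": _demographics(df),
        "group_comparison": comparison_df,
        "correlations": corr,
        "regression": fit_regression(df),
        "lordosis": lordosis_df,
        "test_log": pd.DataFrame(log_rows),
    }


def write_reports(reports: dict[str, object], out_dir: str | Path) -> dict[str, Path]:
    """Write the report bundle as CSVs plus machine-readable JSON mirrors."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name in ("demographics", "group_comparison", "correlations", "lordosis", "test_log"):
        frame: pd.DataFrame = reports[name]  # type: ignore[assignment]
        csv_path = out / f"{name}.csv"
        frame.to_csv(csv_path, index=False)
        frame.to_json(out / f"{name}.json", orient="records", indent=2)
        paths[name] = csv_path
    reg: RegressionReport = reports["regression"]  # type: ignore[assignment]
    reg_table = reg.table.reset_index()
    reg_path = out / "regression.csv"
    reg_table.to_csv(reg_path, index=False)
    model_info = {
        "dependent": reg.dependent,
        "n": reg.n,
        "r_squared": reg.r_squared,
        "adj_r_squared": reg.adj_r_squared,
        "f_pvalue": reg.f_pvalue,
        "durbin_watson": reg.durbin_watson,
        "coefficients": reg_table.to_dict(orient="records"),
    }
    import json

    with open(out / "regression.json", "w") as fh:
        json.dump(model_info, fh, indent=2)
    paths["regression"] = reg_path
    return paths
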