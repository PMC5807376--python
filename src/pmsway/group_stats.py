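"""Two-way (age x gender) group statistics for the control variables.

For every dependent variable (rSTD_k, N_k, sigma_k) a 2x2 between-subjects
ANOVA is computed with Type III sums of squares and sum-to-zero effect
coding, matching the convention of mainstream GLM software for (possibly
unbalanced) factorial designs.  Reported alongside F and p are the partial
eta squared and the observed power at alpha = 0.05 from the noncentral F
distribution with noncentrality F * df1.  Simple-effects post-hoc
comparisons within a significant interaction are Sidak-corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "AnovaResult",
    "normality_tests",
    "levene",
    "two_way_anova",
    "observed_power",
    "sidak",
    "percent_change",
    "posthoc_simple_effects",
    "full_report",
]

_EFFECTS = {
    "C(age_group, Sum)": "age",
    "C(gender, Sum)": "gender",
    "C(age_group, Sum):C(gender, Sum)": "age:gender",
}


@dataclass
class AnovaResult:
    """One dependent variable's two-way ANOVA.

    ``effects`` rows: age, gender, age:gender with F, df1, df2, p,
    partial_eta_sq and observed_power.  ``normality`` and ``levene_p``
    carry the per-cell assumption checks.
    """

    effects: pd.DataFrame
    mse: float
    df_resid: int
    cell_means: pd.Series
    cell_sizes: pd.Series
    normality: pd.DataFrame | None = None
    levene_stat: float = field(default=float("nan"))
    levene_p: float = field(default=float("nan"))


def normality_tests(values_per_cell: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-cell normality checks: Lilliefors (KS-type) and Shapiro-Wilk.

    The Kolmogorov-Smirnov test with estimated mean/SD requires the
    Lilliefors correction, which is what standard GLM software reports.
    Cells with fewer than 3 values yield NaNs with a warning; constant
    cells are flagged degenerate.
    """
    rows = []
    for cell, vals in values_per_cell.items():
        vals = np.asarray(vals, dtype=float)
        row = {"cell": cell, "n": vals.size, "degenerate": False}
        if vals.size < 3:
            warnings.warn(f"cell {cell!r} has fewer than 3 values")
            row.update(ks_stat=np.nan, ks_p=np.nan, sw_stat=np.nan, sw_p=np.nan)
        elif np.ptp(vals) == 0.0:
            row.update(
                ks_stat=np.nan, ks_p=np.nan, sw_stat=np.nan, sw_p=np.nan,
                degenerate=True,
            )
        else:
            ks_stat, ks_p = lilliefors(vals, dist="norm")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sw = sps.shapiro(vals)
            row.update(ks_stat=ks_stat, ks_p=ks_p, sw_stat=sw.statistic, sw_p=sw.pvalue)
        rows.append(row)
    return pd.DataFrame(rows)


def levene(values_per_cell: dict[str, np.ndarray]) -> tuple[float, float]:
    """Levene's test for equality of cell variances (center = mean)."""
    groups = [np.asarray(v, dtype=float) for v in values_per_cell.values()]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("Levene's test needs >= 2 cells with >= 2 values each")
    with np.errstate(divide="ignore", invalid="ignore"):
        stat, p = sps.levene(*groups, center="mean")
    return float(stat), float(p)


def observed_power(F: float, df1: int, df2: int, alpha: float = 0.05) -> float:
    """Post-hoc power from the noncentral F with noncentrality F * df1."""
    if not np.isfinite(F) or F < 0:
        return float("nan")
    crit = sps.f.ppf(1 - alpha, df1, df2)
    return float(1.0 - sps.ncf.cdf(crit, df1, df2, F * df1))


def sidak(p_raw: float, m: int) -> float:
    """Sidak-adjusted p-value for a family of ``m`` comparisons."""
    if not 0 <= p_raw <= 1:
        raise ValueError("p must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(min(1.0, 1.0 - (1.0 - p_raw) ** m))


def percent_change(reference_mean: float, comparison_mean: float) -> float:
    """Relative change of the comparison group mean (reference = 100%)."""
    if reference_mean == 0:
        raise ZeroDivisionError("reference mean is zero; percent change undefined")
    return 100.0 * (comparison_mean - reference_mean) / reference_mean


def _cells(table: pd.DataFrame, value_col: str = "value") -> dict[str, np.ndarray]:
    return {
        f"{a}/{g}": sub[value_col].to_numpy()
        for (a, g), sub in table.groupby(["age_group", "gender"], observed=True)
    }


def two_way_anova(
    table: pd.DataFrame, value_col: str = "value", check_assumptions: bool = True
) -> AnovaResult:
    """2x2 between-subjects ANOVA (Type III SS, sum-to-zero coding).

    ``table`` needs columns ``age_group``, ``gender`` and ``value_col``;
    both factors must have exactly two levels and every cell at least two
    observations (cells may be unbalanced).
    """
    df = table.rename(columns={value_col: "value"})[
        ["value", "age_group", "gender"]
    ].dropna()
    for col in ("age_group", "gender"):
        if df[col].nunique() != 2:
            raise ValueError(f"{col} must have exactly 2 levels")
    sizes = df.groupby(["age_group", "gender"], observed=True)["value"].size()
    if len(sizes) < 4 or (sizes < 2).any():
        raise ValueError("every age x gender cell needs >= 2 observations")

    model = smf.ols(
        "value ~ C(age_group, Sum) * C(gender, Sum)", data=df
    ).fit()
    aov = sm.stats.anova_lm(model, typ=3)
    ss_err = aov.loc["Residual", "sum_sq"]
    df2 = int(aov.loc["Residual", "df"])
    mse = ss_err / df2

    rows = []
    for term, name in _EFFECTS.items():
        ss = aov.loc[term, "sum_sq"]
        df1 = int(aov.loc[term, "df"])
        F = aov.loc[term, "F"]
        p = aov.loc[term, "PR(>F)"]
        rows.append(
            {
                "effect": name,
                "F": F,
                "df1": df1,
                "df2": df2,
                "p": p,
                "partial_eta_sq": ss / (ss + ss_err),
                "observed_power": observed_power(F, df1, df2),
            }
        )
    effects = pd.DataFrame(rows)

    res = AnovaResult(
        effects=effects,
        mse=float(mse),
        df_resid=df2,
        cell_means=df.groupby(["age_group", "gender"], observed=True)["value"].mean(),
        cell_sizes=sizes,
    )
    if check_assumptions:
        cells = _cells(df)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res.normality = normality_tests(cells)
        try:
            res.levene_stat, res.levene_p = levene(cells)
        except ValueError:
            pass
    return res


def posthoc_simple_effects(
    table: pd.DataFrame, result: AnovaResult, value_col: str = "value"
) -> pd.DataFrame:
    """Sidak-corrected pairwise simple-effects comparisons.

    The family comprises the four comparisons nested in the interaction:
    old-vs-young within each gender and female-vs-male within each age
    group, tested with t statistics on the pooled ANOVA error term
    (m = 4 Sidak family).
    """
    df = table.rename(columns={value_col: "value"})[
        ["value", "age_group", "gender"]
    ].dropna()
    means = result.cell_means
    sizes = result.cell_sizes
    ages = sorted(df["age_group"].unique())
    genders = sorted(df["gender"].unique())

    contrasts = []
    for g in genders:
        contrasts.append(((ages[1], g), (ages[0], g), f"{ages[1]}-vs-{ages[0]} within {g}"))
    for a in ages:
        contrasts.append(((a, genders[0]), (a, genders[1]), f"{genders[0]}-vs-{genders[1]} within {a}"))

    m = len(contrasts)
    rows = []
    for c1, c2, desc in contrasts:
        diff = means[c1] - means[c2]
        se = np.sqrt(result.mse * (1.0 / sizes[c1] + 1.0 / sizes[c2]))
        t = diff / se
        p_raw = 2.0 * sps.t.sf(abs(t), result.df_resid)
        rows.append(
            {
                "contrast": desc,
                "mean_diff": diff,
                "t": t,
                "p_raw": p_raw,
                "p_sidak": sidak(p_raw, m),
                "m": m,
            }
        )
    return pd.DataFrame(rows)


def full_report(
    control: pd.DataFrame,
    metadata: pd.DataFrame,
    components: tuple[int, ...] | None = None,
    variables: tuple[str, ...] = ("rSTD", "N", "sigma"),
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ANOVA and post-hoc tables over all variables x components.

    ``control`` is the tidy per-subject table (subject_id, k, rSTD, N,
    sigma, ...), ``metadata`` carries subject_id, age_group, gender.
    Missing values are excluded casewise per variable x component with a
    warning.  Post-hoc simple effects are reported for cells whose
    interaction is significant at ``alpha``.  Percent changes use the
    younger (resp. male) group as the 100% reference.
    """
    merged = control.merge(
        metadata[["subject_id", "age_group", "gender"]], on="subject_id", how="left"
    )
    if merged[["age_group", "gender"]].isna().any().any():
        raise ValueError("metadata missing for some subjects")
    ks = components or tuple(sorted(merged["k"].unique()))

    anova_rows = []
    posthoc_frames = []
    for var in variables:
        if var not in merged.columns:
            continue
        for k in ks:
            sub = merged[merged["k"] == k][["subject_id", var, "age_group", "gender"]]
            n_missing = int(sub[var].isna().sum())
            if n_missing:
                warnings.warn(
                    f"{var} k={k}: excluding {n_missing} subjects with missing values"
                )
            sub = sub.dropna(subset=[var])
            res = two_way_anova(sub.rename(columns={var: "value"}))

            means = res.cell_means
            young_mean = means.xs("young", level="age_group").mean()
            old_mean = means.xs("old", level="age_group").mean()
            male_mean = means.xs("male", level="gender").mean()
            female_mean = means.xs("female", level="gender").mean()
            pct = {
                "age": percent_change(young_mean, old_mean) if young_mean else np.nan,
                "gender": percent_change(male_mean, female_mean) if male_mean else np.nan,
                "age:gender": np.nan,
            }
            for _, erow in res.effects.iterrows():
                anova_rows.append(
                    {
                        "variable": var,
                        "k": k,
                        "effect": erow["effect"],
                        "F": erow["F"],
                        "df1": erow["df1"],
                        "df2": erow["df2"],
                        "p": erow["p"],
                        "partial_eta_sq": erow["partial_eta_sq"],
                        "observed_power": erow["observed_power"],
                        "percent_change": pct[erow["effect"]],
                        "levene_p": res.levene_p,
                        "n": int(res.cell_sizes.sum()),
                    }
                )
            inter_p = res.effects.set_index("effect").loc["age:gender", "p"]
            if inter_p < alpha:
                ph = posthoc_simple_effects(sub.rename(columns={var: "value"}), res)
                ph.insert(0, "variable", var)
                ph.insert(1, "k", k)
                posthoc_frames.append(ph)

    anova_table = pd.DataFrame(anova_rows)
    posthoc_table = (
        pd.concat(posthoc_frames, ignore_index=True)
        if posthoc_frames
        else pd.DataFrame(
            columns=["variable", "k", "contrast", "mean_diff", "t", "p_raw", "p_sidak", "m"]
        )
    )
    return anova_table, posthoc_table
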