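"""Two-factor ANOVA machinery for strain classification and time courses.

Used in two ways: (a) a strain is called a Clock suppressor when the strain x
Clock-genotype interaction is significant — a strain that merely shifts both
wild-type and mutant periods equally is not a suppressor; (b) strain x time
analysis of expression time courses with Tukey HSD post hoc comparisons.
Unbalanced tables use Type II sums of squares (interaction tested last);
balanced tables are decomposition-invariant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

DEFAULT_ALPHA = 0.05


@dataclass
class AnovaResult:
    """F ratios, df pairs and p values for both main effects and the interaction."""

    f_a: float
    f_b: float
    f_interaction: float
    p_a: float
    p_b: float
    p_interaction: float
    df_a: int
    df_b: int
    df_interaction: int
    df_resid: int
    table: pd.DataFrame
    degenerate: bool = False  # zero residual variance with non-zero effect SS


@dataclass
class StrainClassification:
    strain: str
    interaction_p: float
    interaction_f: float
    label: str  # "suppressor" | "non_suppressor"
    degenerate: bool = False


def _check_table(df: pd.DataFrame, a: str, b: str, value: str) -> None:
    for col in (a, b, value):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    if not np.all(np.isfinite(df[value].to_numpy(dtype=float))):
        raise ValueError("values must be finite")
    la, lb = df[a].unique(), df[b].unique()
    if len(la) < 2 or len(lb) < 2:
        raise ValueError("each factor needs >= 2 levels")
    counts = df.groupby([a, b], observed=True).size()
    empty = [
        cell for cell in itertools.product(la, lb) if cell not in counts.index
    ]
    if empty:
        raise ValueError(f"interaction inestimable; empty cells: {empty}")
    n_cells = len(la) * len(lb)
    if len(df) - n_cells < 1:
        raise ValueError("zero residual df: need at least one cell with replication")


def two_way_anova(
    table: pd.DataFrame,
    factor_a: str = "a",
    factor_b: str = "b",
    value: str = "value",
) -> AnovaResult:
    """Two-way fixed-effects ANOVA with interaction (Type II for unbalanced data).

    ``table`` is long-format with one observation per row. Raises when a cell
    of the factor grid is empty (naming the cells) or there is no residual
    df. A table with zero residual variance but non-zero effect variance
    returns infinite F flagged ``degenerate``.
    """
    df = table.rename(columns={factor_a: "_fa", factor_b: "_fb", value: "_y"}).copy()
    df["_y"] = df["_y"].astype(float)
    _check_table(df, "_fa", "_fb", "_y")

    fit = ols("_y ~ C(_fa) * C(_fb)", data=df).fit()
    ss_resid = float(fit.ssr)
    ss_scale = float(((df["_y"] - df["_y"].mean()) ** 2).sum())
    degenerate = ss_scale > 0 and ss_resid <= 1e-12 * ss_scale

    aov = anova_lm(fit, typ=2)
    rows = {
        "A": aov.loc["C(_fa)"],
        "B": aov.loc["C(_fb)"],
        "A:B": aov.loc["C(_fa):C(_fb)"],
        "resid": aov.loc["Residual"],
    }

    def f_and_p(row) -> tuple[float, float]:
        if degenerate:
            return (np.inf, 0.0) if row["sum_sq"] > 1e-12 * max(ss_scale, 1e-300) else (0.0, 1.0)
        return float(row["F"]), float(row["PR(>F)"])

    f_a, p_a = f_and_p(rows["A"])
    f_b, p_b = f_and_p(rows["B"])
    f_ab, p_ab = f_and_p(rows["A:B"])
    out = aov.rename(
        index={"C(_fa)": factor_a, "C(_fb)": factor_b,
               "C(_fa):C(_fb)": f"{factor_a}:{factor_b}"}
    )
    return AnovaResult(
        f_a, f_b, f_ab, p_a, p_b, p_ab,
        int(rows["A"]["df"]), int(rows["B"]["df"]), int(rows["A:B"]["df"]),
        int(rows["resid"]["df"]), out, degenerate,
    )


def classify_strain(
    wt_b6,
    wt_f1,
    clk_b6,
    clk_f1,
    alpha: float = DEFAULT_ALPHA,
    strain: str = "",
) -> StrainClassification:
    """Label a strain a Clock suppressor from four period groups.

    The four groups are wild-type and Clock-mutant animals on the reference
    (B6) and the F1-hybrid background. The strain is a suppressor iff the
    strain x Clock-genotype interaction is significant at ``alpha`` — i.e.
    the mutant period effect differs between backgrounds.
    """
    groups = {
        ("wt", "b6"): wt_b6,
        ("wt", "f1"): wt_f1,
        ("clock", "b6"): clk_b6,
        ("clock", "f1"): clk_f1,
    }
    rows = []
    for (geno, background), values in groups.items():
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise ValueError(f"empty group: {geno}/{background}")
        rows.extend(
            {"genotype": geno, "background": background, "period": v} for v in values
        )
    res = two_way_anova(pd.DataFrame(rows), "genotype", "background", "period")
    label = "suppressor" if res.p_interaction < alpha else "non_suppressor"
    return StrainClassification(
        strain, res.p_interaction, res.f_interaction, label, res.degenerate
    )


@dataclass
class TukeyResult:
    comparisons: pd.DataFrame  # group_i, group_j, diff, ci_low, ci_high, p, significant
    alpha: float


def tukey_hsd(groups, alpha: float = DEFAULT_ALPHA) -> TukeyResult:
    """Tukey honestly-significant-difference simultaneous pairwise comparisons.

    ``groups`` is a sequence of value arrays (>= 2 groups, each with >= 2
    observations). Uses the studentized-range distribution with pooled
    within-group variance; CIs are simultaneous at level 1 - alpha.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(g) < 2 for g in arrays):
        raise ValueError("every group needs >= 2 observations")
    res = stats.tukey_hsd(*arrays)
    ci = res.confidence_interval(confidence_level=1.0 - alpha)
    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            p = float(res.pvalue[i, j])
            rows.append(
                {
                    "group_i": i,
                    "group_j": j,
                    "diff": float(arrays[i].mean() - arrays[j].mean()),
                    "ci_low": float(ci.low[i, j]),
                    "ci_high": float(ci.high[i, j]),
                    "p": p,
                    "significant": p < alpha,
                }
            )
    return TukeyResult(pd.DataFrame(rows), alpha)
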