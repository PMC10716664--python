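"""Comparison layer: two-sample t-tests, mixed-design repeated-measures
ANOVA, and a priori per-frequency pairwise contrasts.

Morphometric state differences use pooled-variance Student t-tests
(two-tailed, df = n1 + n2 - 2).  Evoked magnitudes and thresholds use a
mixed design: swim bladder condition (or reproductive state) as the
between-subject factor and stimulus frequency as the repeated
within-subject factor; Greenhouse-Geisser correction of the repeated
factor is applied by default.  Frequency-specific contrasts are planned
(a priori) comparisons and carry no multiplicity correction — flagged at
alpha = 0.05; interpret the family of flags accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


@dataclass
class ComparisonResult:
    """One test: statistic, degrees of freedom, p-value, labels."""

    test: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    labels: dict = field(default_factory=dict)
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def two_sample_t(group_a, group_b, two_tailed: bool = True) -> ComparisonResult:
    """Pooled-variance Student's t (A vs B); two-tailed by default."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    df = a.size + b.size - 2
    sp2 = (((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df)
    if sp2 == 0.0:
        if np.isclose(a.mean(), b.mean()):
            return ComparisonResult("two_sample_t", 0.0, (float(df),), 1.0)
        return ComparisonResult("two_sample_t", np.inf, (float(df),), 0.0,
                                degenerate=True)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
    if two_tailed:
        p = 2.0 * sps.t.sf(abs(t), df)
    else:
        p = sps.t.sf(abs(t), df)
    return ComparisonResult("two_sample_t", float(t), (float(df),), float(p))


def rm_anova_oneway(
    table: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    within: str = "frequency",
    between: str = "condition",
    correction: bool = True,
    pooled: bool = False,
) -> ComparisonResult:
    """Between-condition F with frequency as the repeated factor.

    Default: subject-level mixed-design ANOVA (Greenhouse-Geisser corrected
    repeated factor).  ``pooled=True`` instead treats every (subject,
    frequency) observation as an independent trial in a two-way fixed-effects
    ANOVA — the trial-pooling convention seen in some electrophysiology
    reports; its denominator df is much larger.
    """
    for col in (dv, subject, within, between):
        if col not in table.columns:
            raise ValueError(f"column {col!r} missing from table")
    cells = table.groupby([subject, within], observed=True)[dv].count().unstack()
    if cells.isna().any().any():
        missing = [(s, f) for (s, f), v in
                   cells.stack(future_stack=True).items() if pd.isna(v)]
        raise ValueError(f"missing (subject, frequency) cells: {missing[:10]}")

    if pooled:
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        d = table.rename(columns={dv: "y", within: "freq", between: "cond"})
        model = ols("y ~ C(cond) + C(freq)", data=d).fit()
        aov = sm.stats.anova_lm(model, typ=2)
        row = aov.loc["C(cond)"]
        return ComparisonResult(
            "anova_pooled", float(row["F"]),
            (float(row["df"]), float(aov.loc["Residual", "df"])),
            float(row["PR(>F)"]), labels={"between": between})

    import pingouin as pg
    aov = pg.mixed_anova(data=table, dv=dv, within=within, subject=subject,
                         between=between, correction=correction)
    row = aov[aov["Source"] == between].iloc[0]
    pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
    return ComparisonResult(
        "mixed_anova", float(row["F"]), (float(row["DF1"]), float(row["DF2"])),
        float(row[pcol]), labels={"between": between})


def pairwise_apriori_t(
    table: pd.DataFrame,
    dv: str = "value",
    group: str = "condition",
    frequency: str = "frequency",
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Unadjusted two-sample t per frequency between the two group levels."""
    groups = sorted(table[group].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {groups}")
    rows = []
    for f, sub in table.groupby(frequency, observed=True):
        a = sub.loc[sub[group] == groups[0], dv].dropna().to_numpy()
        b = sub.loc[sub[group] == groups[1], dv].dropna().to_numpy()
        if a.size < 2 or b.size < 2:
            rows.append({"frequency": f, "t": np.nan, "df": np.nan,
                         "p": np.nan, "significant": False})
            continue
        res = two_sample_t(a, b)
        rows.append({"frequency": f, "t": res.statistic, "df": res.df[0],
                     "p": res.p_value, "significant": res.p_value < alpha})
    return pd.DataFrame(rows)
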