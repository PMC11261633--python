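"""Replicate collapsing and group comparisons.

The testing scheme follows common practice in quantitative fluorescence
studies: per-hemisphere measurements from one brain are technical
replicates and are averaged to one value per fly; samples are gated for
normality with a Kolmogorov–Smirnov test (against a normal with the
sample's own mean and sd — the common packaged behaviour, approximate in
the Lilliefors sense) and for equality of variances (F-test for two
groups, Bartlett for more); two groups are then compared with an
unpaired two-sided t-test (pooled, or Welch when the variance gate
fails) or, failing normality, a two-sided Mann–Whitney U (exact for
combined n <= 20 without ties, normal approximation with tie correction
otherwise); genotype x age designs use a two-way ANOVA (Type-III-style
partial sums of squares with sum-to-zero encoding, so unbalanced designs
do not depend on factor order) with Šidák-adjusted pairwise genotype
contrasts within each age level, ``p_adj = 1 - (1 - p)^m``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import ValidationError

__all__ = [
    "ComparisonResult",
    "collapse_replicates",
    "normality_check",
    "equal_variance_check",
    "sidak_adjust",
    "compare_two_groups",
    "compare_two_way",
]

REPLICATE_KEYS = ["fly_id", "hemisphere", "metric"]
GROUP_COLS = ["genotype", "age"]


@dataclass
class ComparisonResult:
    """Outcome of one statistical comparison, with its decision trail."""

    metric: str
    contrast: str
    test_name: str
    statistic: float
    p_value: float
    adjusted_p: float
    alpha: float
    normality_p: float = float("nan")
    decision_path: str = ""

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError("p_value must lie in [0, 1]")
        if self.adjusted_p < self.p_value - 1e-12:
            raise ValidationError("adjusted_p must be >= p_value")
        if not self.decision_path:
            raise ValidationError("decision_path must be non-empty")

    @property
    def significant(self) -> bool:
        return self.adjusted_p < self.alpha

    def to_row(self) -> dict:
        return {
            "metric": self.metric,
            "contrast": self.contrast,
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "adjusted_p": self.adjusted_p,
            "alpha": self.alpha,
            "normality_p": self.normality_p,
            "significant": self.significant,
            "decision_path": self.decision_path,
        }


def collapse_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Average per-hemisphere technical replicates to one row per fly.

    Expects a long table with columns ``fly_id, hemisphere, metric,
    value`` plus optional grouping columns (genotype, age) that must be
    constant within a fly.  Duplicate (fly, hemisphere, metric) rows are
    an error; single-hemisphere flies pass through unchanged.
    """
    required = set(REPLICATE_KEYS + ["value"])
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"table lacks columns {sorted(missing)}")
    dup = table.duplicated(subset=REPLICATE_KEYS)
    if dup.any():
        rows = table.loc[dup, REPLICATE_KEYS].to_dict("records")
        raise ValidationError(f"duplicate replicate rows: {rows[:3]}")
    keep = [c for c in GROUP_COLS if c in table.columns]
    grouped = (
        table.groupby(["fly_id", "metric"] + keep, sort=True, as_index=False)["value"]
        .mean()
    )
    return grouped[["fly_id"] + keep + ["metric", "value"]]


def normality_check(samples: Sequence[float]) -> float:
    """Kolmogorov–Smirnov p-value against a fitted normal.

    Parameters are estimated from the sample (mean, sd with ddof=1).  A
    constant sample is degenerate and returns p = 0 (treated as clearly
    non-normal).  Requires n >= 3.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 3:
        raise ValidationError("normality check needs n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(sps.kstest(x, "norm", args=(x.mean(), sd)).pvalue)


def equal_variance_check(*groups: Sequence[float]) -> Tuple[str, float]:
    """Equality-of-variances gate: F-test for 2 groups, Bartlett for more."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) == 2:
        a, b = arrs
        va, vb = a.var(ddof=1), b.var(ddof=1)
        if vb == 0 and va == 0:
            return "F-test", 1.0
        if vb == 0 or va == 0:
            return "F-test", 0.0
        f = va / vb
        dfn, dfd = a.size - 1, b.size - 1
        p = 2.0 * min(sps.f.cdf(f, dfn, dfd), sps.f.sf(f, dfn, dfd))
        return "F-test", float(min(1.0, p))
    stat, p = sps.bartlett(*arrs)
    return "Bartlett", float(p)


def sidak_adjust(p: float, m: int) -> float:
    """Šidák correction for m comparisons: ``1 - (1 - p)^m``."""
    if m < 1:
        raise ValidationError("m must be >= 1")
    if not (0.0 <= p <= 1.0):
        raise ValidationError("p must lie in [0, 1]")
    if p >= 1.0:
        return 1.0
    return float(min(1.0, -math.expm1(m * math.log1p(-p))))


def _mann_whitney(a: np.ndarray, b: np.ndarray) -> Tuple[float, float, str]:
    """Two-sided Mann–Whitney U; exact for small untied samples."""
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    exact = (a.size + b.size) <= 20 and not ties
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), method


def compare_two_groups(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = 0.05,
    labels: Tuple[str, str] = ("A", "B"),
    metric: str = "",
) -> ComparisonResult:
    """Normality-gated two-sample comparison.

    Both groups passing the KS normality gate (p >= alpha) leads to an
    unpaired two-sided t-test — pooled variance unless the variance gate
    fails, then Welch.  Otherwise a two-sided Mann–Whitney U is used.
    The decision trail records every gate outcome.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValidationError("each group needs n >= 3")
    pa, pb = normality_check(a), normality_check(b)
    path = [f"KS normality: p_{labels[0]}={pa:.4g}, p_{labels[1]}={pb:.4g} (alpha={alpha})"]
    if pa >= alpha and pb >= alpha:
        var_test, pv = equal_variance_check(a, b)
        if pv >= alpha:
            stat, p = sps.ttest_ind(a, b, equal_var=True)
            name = "unpaired t-test (pooled)"
            path.append(f"{var_test} equal variances: p={pv:.4g} -> pooled t-test")
        else:
            stat, p = sps.ttest_ind(a, b, equal_var=False)
            name = "unpaired t-test (Welch)"
            path.append(f"{var_test} equal variances: p={pv:.4g} -> Welch t-test")
    else:
        stat, p, method = _mann_whitney(a, b)
        name = f"Mann-Whitney U ({method})"
        path.append(f"normality failed -> Mann-Whitney U, {method} p")
    return ComparisonResult(
        metric=metric,
        contrast=f"{labels[0]} vs {labels[1]}",
        test_name=name,
        statistic=float(stat),
        p_value=float(p),
        adjusted_p=float(p),
        alpha=alpha,
        normality_p=float(min(pa, pb)),
        decision_path=" ; ".join(path),
    )


def compare_two_way(
    table: pd.DataFrame,
    metric: str = "",
    factors: Tuple[str, str] = ("genotype", "age"),
    value_col: str = "value",
    alpha: float = 0.05,
) -> list:
    """Two-way ANOVA with Šidák-adjusted within-age genotype contrasts.

    ``table`` holds one row per fly with the two factor columns and the
    value column.  Main effects and interaction come from a Type-III
    ANOVA with sum-to-zero encoding; pairwise genotype contrasts within
    each age level use the model's residual mean square and degrees of
    freedom, with Šidák adjustment over the total number of contrasts.
    """
    fa, fb = factors
    for col in (fa, fb, value_col):
        if col not in table.columns:
            raise ValidationError(f"table lacks column {col!r}")
    df = table[[fa, fb, value_col]].rename(columns={value_col: "value"}).copy()
    levels_a = sorted(df[fa].unique())
    levels_b = sorted(df[fb].unique())
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValidationError("each factor needs at least 2 levels")
    sizes = df.groupby([fa, fb]).size()
    for la in levels_a:
        for lb in levels_b:
            if (la, lb) not in sizes.index:
                raise ValidationError(f"empty design cell: {fa}={la}, {fb}={lb}")

    model = smf.ols(f"value ~ C({fa}, Sum) * C({fb}, Sum)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=3)
    mse = float(model.mse_resid)
    dof = float(model.df_resid)

    results = []
    for term, label in (
        (f"C({fa}, Sum)", f"main:{fa}"),
        (f"C({fb}, Sum)", f"main:{fb}"),
        (f"C({fa}, Sum):C({fb}, Sum)", f"interaction:{fa}x{fb}"),
    ):
        p = float(aov.loc[term, "PR(>F)"])
        results.append(ComparisonResult(
            metric=metric,
            contrast=label,
            test_name="two-way ANOVA (Type III)",
            statistic=float(aov.loc[term, "F"]),
            p_value=p,
            adjusted_p=p,
            alpha=alpha,
            decision_path=(
                "two-way ANOVA, partial (Type-III-style) SS, sum-to-zero encoding"
            ),
        ))

    cells = df.groupby([fa, fb])["value"].agg(["mean", "count"])
    contrasts = []
    for lb in levels_b:
        for i in range(len(levels_a)):
            for j in range(i + 1, len(levels_a)):
                contrasts.append((levels_a[i], levels_a[j], lb))
    m = len(contrasts)
    for la1, la2, lb in contrasts:
        m1, n1 = cells.loc[(la1, lb), "mean"], cells.loc[(la1, lb), "count"]
        m2, n2 = cells.loc[(la2, lb), "mean"], cells.loc[(la2, lb), "count"]
        se = math.sqrt(mse * (1.0 / n1 + 1.0 / n2))
        tstat = (m1 - m2) / se if se > 0 else 0.0
        p = float(2.0 * sps.t.sf(abs(tstat), dof)) if se > 0 else 1.0
        results.append(ComparisonResult(
            metric=metric,
            contrast=f"{la1} vs {la2} | {fb}={lb}",
            test_name="Sidak-adjusted cell contrast (pooled residual MSE)",
            statistic=float(tstat),
            p_value=p,
            adjusted_p=sidak_adjust(p, m),
            alpha=alpha,
            decision_path=(
                f"cell-mean t on residual MSE (df={dof:.0f}) ; "
                f"Sidak over m={m} contrasts"
            ),
        ))
    return results
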