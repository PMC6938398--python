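"""Statistical layer: group comparisons, multiplicity, correlation, ANCOVA.

Thin, opinionated wrappers over scipy.stats and statsmodels implementing the
analysis conventions used throughout this package: two-group comparisons via
Student's t when a Shapiro-Wilk gate (alpha 0.05 per group, overridable)
accepts normality and Mann-Whitney U (Wilcoxon signed-rank when paired)
otherwise; one-way (optionally repeated-measures) ANOVA with post-hoc Tukey
or Holm-adjusted pairwise t-tests; a 3-SD outlier rule applied in a single
pass; least-squares correlation reporting r^2 with an F-test on the slope;
and an ANCOVA homogeneity-of-regression-slopes test (t for two groups, F
for more).  Significance is assessed at p < 0.05; every result records
which test actually ran.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


@dataclass
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    parametric: bool
    normality_p: tuple[float, ...] = ()

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass
class AnovaResult:
    f_statistic: float
    p_omnibus: float
    tukey: pd.DataFrame                   # pairwise Tukey-adjusted p values
    holm: pd.DataFrame                    # pairwise t-tests, Holm-adjusted
    repeated: bool


@dataclass
class CorrelationResult:
    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    p_slope: float
    n: int


@dataclass
class AncovaResult:
    slopes: dict
    statistic: float
    p_homogeneity: float
    test_name: str                        # "t" (2 groups) or "F"
    df: tuple[int, int] = field(default=(0, 0))


def remove_outliers(values):
    """Single-pass 3-SD outlier rule.

    Mean and (sample) SD are computed once on the full input; points more
    than three SDs from the mean are removed.  No iteration.  With zero SD
    nothing is removed.
    """
    arr = np.asarray(values, dtype=float)
    if len(arr) < 3:
        raise ValueError("need at least 3 values for the outlier rule")
    sd = float(np.std(arr, ddof=1))
    if sd == 0.0:
        return arr.copy(), arr[:0].copy()
    dev = np.abs(arr - arr.mean())
    keep = dev <= 3.0 * sd
    return arr[keep], arr[~keep]


def _normality_gate(samples, alpha=ALPHA):
    pvals = []
    for s in samples:
        if len(s) < 3 or np.ptp(s) == 0:
            pvals.append(float("nan"))
            continue
        pvals.append(float(sps.shapiro(s).pvalue))
    ok = all(math.isnan(p) or p > alpha for p in pvals)
    return ok, tuple(pvals)


def compare_groups(a, b, paired: bool = False,
                   parametric: bool | None = None) -> ComparisonResult:
    """Two-group comparison with an automatic parametric gate.

    ``parametric=None`` runs Shapiro-Wilk on each group (on the differences
    when paired) and picks Student's t when normality is not rejected,
    otherwise Mann-Whitney U (Wilcoxon signed-rank when paired).  Two-sided
    p values throughout.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if paired and len(a) != len(b):
        raise ValueError("paired groups must have matching lengths")

    norm_p: tuple[float, ...] = ()
    if parametric is None:
        parametric, norm_p = _normality_gate([a - b] if paired else [a, b])

    if parametric:
        if paired:
            diff = a - b
            if np.ptp(diff) == 0:  # zero-variance differences: t is 0 by definition
                return ComparisonResult("paired t-test", 0.0, 1.0, True, norm_p)
            res = sps.ttest_rel(a, b)
            return ComparisonResult("paired t-test", float(res.statistic),
                                    float(res.pvalue), True, norm_p)
        res = sps.ttest_ind(a, b)
        return ComparisonResult("t-test", float(res.statistic),
                                float(res.pvalue), True, norm_p)
    if paired:
        diff = a - b
        if np.ptp(diff) == 0 and np.all(diff == 0):
            return ComparisonResult("wilcoxon", 0.0, 1.0, False, norm_p)
        res = sps.wilcoxon(a, b)
        return ComparisonResult("wilcoxon", float(res.statistic),
                                float(res.pvalue), False, norm_p)
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return ComparisonResult("mann-whitney", float(res.statistic),
                            float(res.pvalue), False, norm_p)


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p values (monotone, clipped at 1)."""
    from statsmodels.stats.multitest import multipletests
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="holm")[1]


def anova_tukey(groups, repeated: bool = False) -> AnovaResult:
    """One-way (or repeated-measures) ANOVA with post-hoc tables.

    Returns the omnibus F and p, Tukey-HSD-adjusted pairwise p values, and
    the alternative Holm-adjusted pairwise t-test table (paired t-tests when
    ``repeated``).  Repeated measures require equal group lengths (one value
    per subject per condition); no sphericity correction is applied.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("need at least 3 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 observations")

    labels = [f"g{i}" for i in range(len(groups))]
    if repeated:
        if len({len(g) for g in groups}) != 1:
            raise ValueError("repeated measures require equal group lengths")
        from statsmodels.stats.anova import AnovaRM
        n = len(groups[0])
        long = pd.DataFrame({
            "subject": np.tile(np.arange(n), len(groups)),
            "condition": np.repeat(labels, n),
            "value": np.concatenate(groups)})
        table = AnovaRM(long, "value", "subject", within=["condition"]).fit().anova_table
        f_stat = float(table["F Value"].iloc[0])
        p_omni = float(table["Pr > F"].iloc[0])
    else:
        f_stat, p_omni = (float(v) for v in sps.f_oneway(*groups))

    from statsmodels.stats.multicomp import pairwise_tukeyhsd
    tk = pairwise_tukeyhsd(np.concatenate(groups),
                           np.repeat(labels, [len(g) for g in groups]))
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    tukey = tukey.rename(columns={"p-adj": "p_adj"})[["group1", "group2", "p_adj"]]
    tukey["p_adj"] = tukey["p_adj"].astype(float)

    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            if repeated:
                res = sps.ttest_rel(groups[i], groups[j])
            else:
                res = sps.ttest_ind(groups[i], groups[j])
            rows.append({"group1": labels[i], "group2": labels[j],
                         "p_raw": float(res.pvalue)})
    holm = pd.DataFrame(rows)
    holm["p_holm"] = holm_adjust(holm["p_raw"].to_numpy())
    return AnovaResult(f_stat, p_omni, tukey, holm, repeated)


def correlate(x, y) -> CorrelationResult:
    """Least-squares line with r^2 and the F-test for a zero slope.

    For simple regression the F statistic is the square of the slope's t
    statistic and shares its p value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x must not be constant")
    res = sps.linregress(x, y)
    if res.stderr == 0:
        f_stat = math.inf
    else:
        f_stat = (res.slope / res.stderr) ** 2
    return CorrelationResult(float(res.slope), float(res.intercept),
                             float(res.rvalue) ** 2, float(f_stat),
                             float(res.pvalue), len(x))


def ancova_homogeneity(x, y, group_labels) -> AncovaResult:
    """Homogeneity-of-regression-slopes test across groups.

    Fits the interaction model (separate slope and intercept per group)
    against the common-slope model (separate intercepts only) and tests the
    slope-equality null with a partial F-test; with exactly two groups the
    equivalent t statistic (signed square root of F) is reported.
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    labels = np.asarray(group_labels)
    uniq = list(pd.unique(labels))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    for u in uniq:
        sel = labels == u
        if sel.sum() < 3:
            raise ValueError(f"group {u!r} needs at least 3 points")
        if np.ptp(x[sel]) == 0:
            raise ValueError(f"group {u!r} has constant x (degenerate)")

    g = len(uniq)
    n = len(x)
    dummies = np.column_stack([(labels == u).astype(float) for u in uniq])
    reduced = sm.OLS(y, np.column_stack([dummies, x])).fit()
    full = sm.OLS(y, np.column_stack([dummies, dummies * x[:, None]])).fit()

    slopes = {u: float(full.params[g + i]) for i, u in enumerate(uniq)}
    df1, df2 = g - 1, n - 2 * g
    rss_f, rss_r = float(full.ssr), float(reduced.ssr)
    if rss_f <= 1e-12 * max(1.0, float(np.var(y) * n)):
        # perfect fits (noise-free input): identical slopes, nothing to test
        if rss_r - rss_f <= 1e-12 * max(1.0, float(np.var(y) * n)):
            return AncovaResult(slopes, 0.0, 1.0, "t" if g == 2 else "F", (df1, df2))
        return AncovaResult(slopes, math.inf, 0.0, "t" if g == 2 else "F", (df1, df2))
    f_stat = ((rss_r - rss_f) / df1) / (rss_f / df2)
    p = float(sps.f.sf(f_stat, df1, df2))
    if g == 2:
        t_stat = math.copysign(math.sqrt(f_stat),
                               slopes[uniq[0]] - slopes[uniq[1]])
        return AncovaResult(slopes, t_stat, p, "t", (df1, df2))
    return AncovaResult(slopes, float(f_stat), p, "F", (df1, df2))


def stats_report(results: dict) -> pd.DataFrame:
    """Flatten named comparison results into the report table format."""
    rows = []
    for name, res in results.items():
        rows.append({"test": res.test_name, "comparison": name,
                     "statistic": res.statistic, "p_raw": res.p_value,
                     "significant": res.p_value < ALPHA})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = holm_adjust(df["p_raw"].to_numpy())
        df["significant_adj"] = df["p_adj"] < ALPHA
    return df
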