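"""Cohort-level comparisons: rank tests by group, pattern contingency
tests, Spearman correlation matrices, and per-radius NMS group summaries.

Conventions: all tests are two-sided at the 5% level with no multiplicity
adjustment. Two-group contrasts use the Wilcoxon rank-sum test (exact
null distribution when both groups are small and tie-free, otherwise the
tie-corrected normal approximation); more than two groups use the
Kruskal-Wallis test. Contingency tables use Pearson's chi-squared unless
an expected count falls below 5, in which case a 2x2 table switches to
Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

EXACT_MAX_N = 25  # per-group size up to which the exact rank-sum null is used


@dataclass
class GroupComparison:
    metric: str
    grouping: str
    groups: list = field(default_factory=list)
    n: list = field(default_factory=list)
    median: list = field(default_factory=list)
    iqr: list = field(default_factory=list)
    test: str = ""
    statistic: float = float("nan")
    p_value: float = float("nan")


def compare_metric_by_group(
    values,
    groups,
    metric: str = "metric",
    grouping: str = "group",
) -> GroupComparison:
    """Two-sided rank test of a metric across groups.

    Missing values are dropped pairwise with their group labels. Raises
    if fewer than two groups remain or any group is empty.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    keep = ~np.isnan(v)
    v, g = v[keep], g[keep]
    labels = sorted(pd.unique(g).tolist())
    if len(labels) < 2:
        raise ValueError("need at least two non-empty groups")
    samples = [v[g == lab] for lab in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group needs at least one observation")

    out = GroupComparison(metric=metric, grouping=grouping, groups=labels)
    for s in samples:
        out.n.append(int(len(s)))
        out.median.append(float(np.median(s)))
        q1, q3 = np.percentile(s, [25, 75])
        out.iqr.append(float(q3 - q1))

    if len(labels) == 2:
        a, b = samples
        ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = "exact" if (max(len(a), len(b)) <= EXACT_MAX_N and not ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        out.test = f"wilcoxon_rank_sum[{method}]"
        out.statistic, out.p_value = float(res.statistic), float(res.pvalue)
    else:
        res = stats.kruskal(*samples)
        out.test = "kruskal_wallis"
        out.statistic, out.p_value = float(res.statistic), float(res.pvalue)
    return out


def pattern_test(table) -> tuple[str, float, float]:
    """Association test for a pattern x outcome contingency table.

    Pearson's chi-squared when every expected count is >= 5; otherwise
    Fisher's exact test for 2x2 tables. Larger sparse tables fall back
    to chi-squared, flagged in the returned test name.
    Returns ``(test_name, statistic, p_value)``.
    """
    t = np.asarray(table, dtype=float)
    if t.sum() == 0:
        raise ValueError("empty contingency table")
    expected = stats.contingency.expected_freq(t)
    if (expected >= 5).all():
        chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
        return "chi_squared", float(chi2), float(p)
    if t.shape == (2, 2):
        res = stats.fisher_exact(t)
        return "fisher_exact", float(res[0]), float(res[1])
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return "chi_squared[low_expected_counts]", float(chi2), float(p)


def correlation_matrix(metrics: pd.DataFrame, min_pairs: int = 3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Spearman correlation matrix with p-values.

    Pairs with fewer than ``min_pairs`` complete observations, or with a
    constant column, get NaN. The diagonal is 1 with p = 0.
    """
    cols = list(metrics.columns)
    k = len(cols)
    rho = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    for i in range(k):
        rho[i, i], pval[i, i] = 1.0, 0.0
        for j in range(i + 1, k):
            pair = metrics[[cols[i], cols[j]]].dropna()
            if len(pair) < min_pairs:
                continue
            x, y = pair.iloc[:, 0], pair.iloc[:, 1]
            if x.nunique() < 2 or y.nunique() < 2:
                continue
            res = stats.spearmanr(x, y)
            rho[i, j] = rho[j, i] = float(res.statistic)
            pval[i, j] = pval[j, i] = float(res.pvalue)
    return (
        pd.DataFrame(rho, index=cols, columns=cols),
        pd.DataFrame(pval, index=cols, columns=cols),
    )


def summarize_nms_by_group(
    curves: pd.DataFrame,
    clinical: pd.DataFrame,
    group_col: str = "pcr",
    reference_class: str = "immune",
) -> pd.DataFrame:
    """Median NMS per radius per outcome group (the radar-plot table).

    Missing NMS values are excluded radius-wise; each cell reports the
    number of contributing patients.
    """
    nms_rows = curves[(curves["metric"] == "nms") & (curves["reference_class"] == reference_class)]
    merged = nms_rows.merge(clinical[["patient_id", group_col]], on="patient_id")
    groups = sorted(merged[group_col].dropna().unique().tolist())
    if not groups:
        raise ValueError("no outcome groups")
    rows = []
    for grp_val in groups:
        sub = merged[merged[group_col] == grp_val]
        if sub["patient_id"].nunique() == 0:
            raise ValueError(f"empty group {grp_val!r}")
        for radius, rsub in sub.groupby("radius", sort=True):
            v = rsub["value"].dropna()
            rows.append(
                {
                    "group": grp_val,
                    "radius": float(radius),
                    "median_nms": float(v.median()) if len(v) else np.nan,
                    "n": int(len(v)),
                }
            )
    return pd.DataFrame(rows)
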