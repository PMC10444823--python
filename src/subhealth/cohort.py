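"""Cohort-level descriptive and inferential statistics.

Covers the group comparisons of the physical-examination tables:
distribution-guided single imputation, two-sample t tests (raw or from
printed summaries), chi-square tests (Yates-corrected for 2×2), the
tie-corrected rank test on ordinal grade count tables, symptom prevalence
ranking and the 11-cluster cumulative-frequency aggregation against SV
morphology grades.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "impute_column",
    "ttest_ind",
    "chisq_test",
    "rank_test_ordinal",
    "grade_percentages",
    "symptom_frequencies",
    "cluster_by_grade",
    "CLUSTERS",
]

CLUSTERS = (
    "mental psyche",
    "cold and heat",
    "sweating",
    "head",
    "chest and abdomen",
    "diet",
    "taste",
    "coughing-up phlegm",
    "passing stool and urinating",
    "pain",
    "menstruation",
)


def impute_column(values: pd.Series, alpha: float = 0.05) -> pd.Series:
    """Single imputation guided by the distribution of the observed values.

    Shapiro–Wilk at ``alpha``: mean imputation when normality is not
    rejected, median otherwise.  Observed values are never modified.
    """
    observed = values.dropna()
    if len(observed) == 0:
        raise ValueError("cannot impute an all-missing column")
    if len(observed) == len(values):
        return values.copy()
    if len(observed) < 3:
        raise ValueError("need at least 3 observed values to assess the distribution")
    _, p = stats.shapiro(observed.to_numpy(float))
    fill = observed.mean() if p >= alpha else observed.median()
    return values.fillna(fill)


def _as_stats(group) -> tuple[float, float, int] | None:
    if isinstance(group, tuple) and len(group) == 3:
        return float(group[0]), float(group[1]), int(group[2])
    return None


def ttest_ind(group1, group2, equal_var: bool = True) -> tuple[float, float]:
    """Two-sample t test, two-sided; pooled variance by default.

    Each group is either a raw sample or a printed-summary tuple
    ``(mean, sd, n)``, so statistics published as mean ± SD are directly
    checkable.  ``equal_var=False`` gives Welch's test.
    """
    s1, s2 = _as_stats(group1), _as_stats(group2)
    if (s1 is None) != (s2 is None):
        raise ValueError("give both groups as raw samples or both as (mean, sd, n)")
    if s1 is not None:
        if s1[2] < 2 or s2[2] < 2:
            raise ValueError("each group needs n >= 2")
        res = stats.ttest_ind_from_stats(*s1, *s2, equal_var=equal_var)
    else:
        a, b = np.asarray(group1, float), np.asarray(group2, float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each group needs n >= 2")
        res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def chisq_test(table) -> tuple[float, float]:
    """Pearson chi-square on an r×c count table; Yates-corrected when 2×2."""
    counts = np.asarray(table, float)
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("zero marginal total in the contingency table")
    correction = counts.shape == (2, 2)
    res = stats.chi2_contingency(counts, correction=correction)
    return float(res.statistic), float(res.pvalue)


def rank_test_ordinal(table) -> tuple[float, float]:
    """Tie-corrected rank test on a groups × ordered-grades count table.

    Expands the counts to mid-ranks and computes the Kruskal–Wallis H
    statistic with the tie correction 1 − Σ(t³−t)/(N³−N); for two groups
    this equals the squared standardized Mann–Whitney statistic.  The p
    value is from the χ² reference with (groups − 1) degrees of freedom.
    """
    counts = np.asarray(table, float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("need a groups × grades table with at least 2 grades")
    row_n = counts.sum(axis=1)
    if np.any(row_n == 0):
        raise ValueError("a group has zero total count")
    col_n = counts.sum(axis=0)
    N = counts.sum()
    cum = np.concatenate([[0.0], np.cumsum(col_n)])
    midrank = cum[:-1] + (col_n + 1) / 2.0
    R = counts @ midrank
    H = 12.0 / (N * (N + 1)) * np.sum(R**2 / row_n) - 3.0 * (N + 1)
    tie = 1.0 - np.sum(col_n**3 - col_n) / (N**3 - N)
    if tie <= 0:
        raise ValueError("all observations share one grade")
    H /= tie
    df = counts.shape[0] - 1
    return float(H), float(stats.chi2.sf(H, df))


def grade_percentages(table, decimals: int = 1) -> pd.DataFrame:
    """Within-group percentages of a groups × grades count table."""
    counts = pd.DataFrame(table).astype(float)
    return (counts.div(counts.sum(axis=1), axis=0) * 100).round(decimals)


def symptom_frequencies(
    records: pd.DataFrame, n_subjects: int, top: int | None = None
) -> pd.DataFrame:
    """Ranked symptom prevalences (percent of subjects with severity ≥ 1).

    ``records`` is a long table with columns subject / symptom / severity;
    a subject counts once per symptom regardless of severity.  Ties in
    percentage are broken alphabetically.
    """
    if n_subjects <= 0:
        raise ValueError("n_subjects must be positive")
    pos = records[records["severity"] >= 1]
    counts = pos.groupby("symptom")["subject"].nunique()
    out = (
        pd.DataFrame({"n_positive": counts})
        .assign(percent=lambda d: d["n_positive"] / n_subjects * 100)
        .reset_index()
        .sort_values(["percent", "symptom"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    return out.head(top) if top is not None else out


def cluster_by_grade(
    records: pd.DataFrame,
    cluster_map: dict[str, str],
    sv_grades: pd.DataFrame,
) -> pd.DataFrame:
    """Cumulative symptom frequency per (symptom cluster, SV grade level).

    For every grade level of every morphology dimension present in
    ``sv_grades`` (e.g. T1–T3, L1–L3, W1–W3), sums positive symptom
    occurrences per cluster over the subjects holding that grade.
    Symptoms absent from ``cluster_map`` go to an explicit "unmapped"
    bucket with a warning.
    """
    pos = records[records["severity"] >= 1].copy()
    unmapped = sorted(set(pos["symptom"]) - set(cluster_map))
    if unmapped:
        warnings.warn(f"symptoms without a cluster mapping: {unmapped}")
    pos["cluster"] = pos["symptom"].map(lambda s: cluster_map.get(s, "unmapped"))
    levels = [lv for dim in sv_grades.columns for lv in sorted(sv_grades[dim].unique())]
    clusters = [c for c in CLUSTERS if c in set(pos["cluster"])]
    if unmapped:
        clusters.append("unmapped")
    out = pd.DataFrame(0, index=clusters, columns=levels, dtype=int)
    for dim in sv_grades.columns:
        grade_of = sv_grades[dim]
        joined = pos.assign(grade=pos["subject"].map(grade_of))
        tab = joined.groupby(["cluster", "grade"]).size()
        for (cl, gr), cnt in tab.items():
            out.loc[cl, gr] = int(cnt)
    return out.rename_axis(index="cluster", columns="grade")
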