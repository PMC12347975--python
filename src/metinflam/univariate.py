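"""Between-group univariate screening.

Test selection mirrors the study's scheme: Student's t / Mann-Whitney U for
continuous variables (parametric branch gated on per-group Shapiro-Wilk
normality at alpha = 0.05), chi-square / Fisher's exact for nominal
variables (exact test when any expected cell < 5, 2x2 only), and one-way
ANOVA / Kruskal-Wallis across the four ordinal severity stages. The branch
actually taken is always recorded. No multiple-testing correction is
applied; the screening report states how many tests were run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDataError, ValidationError

__all__ = [
    "TestResult",
    "compare_continuous",
    "compare_categorical",
    "compare_across_stages",
    "screen",
]

logger = logging.getLogger(__name__)

_SHAPIRO_ALPHA = 0.05
_MIN_SHAPIRO_N = 3


@dataclass
class TestResult:
    """Outcome of one hypothesis test, with the branch that produced it."""

    test_name: str
    statistic: float
    p_value: float
    group_summaries: list = field(default_factory=list)
    n_used: tuple = ()

    def __post_init__(self):
        if not (0 <= self.p_value <= 1 or np.isnan(self.p_value)):
            raise ValidationError(f"p-value out of [0,1]: {self.p_value}")


def _clean(values) -> np.ndarray:
    a = np.asarray(pd.to_numeric(pd.Series(values), errors="coerce"), dtype=float)
    return a[np.isfinite(a)]


def _normalish(a: np.ndarray, alpha: float = _SHAPIRO_ALPHA) -> bool:
    """Shapiro-Wilk gate; groups too small (or constant) fail the gate."""
    if len(a) < _MIN_SHAPIRO_N or np.ptp(a) == 0:
        return False
    return stats.shapiro(a).pvalue > alpha


def _summary(a: np.ndarray) -> dict:
    return {"mean": float(np.mean(a)), "sd": float(np.std(a, ddof=1)),
            "n": int(len(a))}


def compare_continuous(values_a, values_b, *,
                       normality_alpha: float = _SHAPIRO_ALPHA) -> TestResult:
    """Two-group comparison of a continuous variable.

    Parametric (Student's t, pooled variance) when both groups pass the
    Shapiro-Wilk check at `normality_alpha`; otherwise two-sided
    Mann-Whitney U. Missing values are dropped per group (complete cases).
    """
    a, b = _clean(values_a), _clean(values_b)
    if len(a) < 2 or len(b) < 2:
        raise DegenerateDataError("need >= 2 non-missing values per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        raise DegenerateDataError("all values identical in both groups")
    parametric = _normalish(a, normality_alpha) and _normalish(b, normality_alpha)
    if parametric:
        res = stats.ttest_ind(a, b, equal_var=True)
        name = "t-student"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        name = "mann-whitney-u"
    return TestResult(test_name=name, statistic=float(res.statistic),
                      p_value=float(res.pvalue),
                      group_summaries=[_summary(a), _summary(b)],
                      n_used=(len(a), len(b)))


def compare_categorical(counts) -> TestResult:
    """Chi-square test of homogeneity on a 2xk contingency table, switching
    to Fisher's exact test (2x2 only) when any expected cell < 5.

    Yates continuity correction is applied on the 2x2 chi-square branch.
    """
    table = np.asarray(counts)
    if table.size == 0 or table.sum() == 0:
        raise DegenerateDataError("empty contingency table")
    if (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        if not np.allclose(table, np.round(table)) or (table < 0).any():
            raise ValidationError("counts must be non-negative integers")
        table = np.round(table).astype(int)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateDataError("a margin of the table is empty")
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).any() and table.shape == (2, 2):
        res = stats.fisher_exact(table)
        return TestResult(test_name="fisher-exact",
                          statistic=float(res.statistic),
                          p_value=float(res.pvalue),
                          group_summaries=table.tolist(),
                          n_used=tuple(int(x) for x in table.sum(axis=1)))
    if (expected < 5).any():
        logger.warning("expected cell < 5 in a %sx%s table; exact test "
                       "unavailable beyond 2x2, using chi-square", *table.shape)
    res = stats.chi2_contingency(table, correction=(table.shape == (2, 2)))
    return TestResult(test_name="chi-square", statistic=float(res.statistic),
                      p_value=float(res.pvalue),
                      group_summaries=table.tolist(),
                      n_used=tuple(int(x) for x in table.sum(axis=1)))


def compare_across_stages(groups, *,
                          normality_alpha: float = _SHAPIRO_ALPHA) -> TestResult:
    """Omnibus comparison across >= 2 ordinal severity groups.

    One-way ANOVA when every group passes the normality gate, else
    Kruskal-Wallis. Groups with < 2 complete cases are excluded.
    """
    cleaned = [_clean(g) for g in groups]
    cleaned = [g for g in cleaned if len(g) >= 2]
    if len(cleaned) < 2:
        raise DegenerateDataError("fewer than two groups with >= 2 values")
    if all(np.ptp(g) == 0 for g in cleaned) and len({g[0] for g in cleaned}) == 1:
        raise DegenerateDataError("all values identical in all groups")
    if all(_normalish(g, normality_alpha) for g in cleaned):
        res = stats.f_oneway(*cleaned)
        name = "one-way-anova"
    else:
        res = stats.kruskal(*cleaned)
        name = "kruskal-wallis"
    statistic, pvalue = float(res.statistic), float(res.pvalue)
    if np.isnan(pvalue) and statistic <= 1e-12:
        # identical group means: float cancellation can push F fractionally
        # below zero, where scipy reports nan instead of the null p = 1
        statistic, pvalue = 0.0, 1.0
    return TestResult(test_name=name, statistic=statistic,
                      p_value=pvalue,
                      group_summaries=[_summary(g) for g in cleaned],
                      n_used=tuple(len(g) for g in cleaned))


def screen(cohort: pd.DataFrame, outcome: str, *,
           variables: list[str] | None = None,
           alpha: float = 0.05) -> pd.DataFrame:
    """Descriptive-table-style screening of lab variables against a binary
    outcome ("histopathological" -> perforated, "surgical" -> complicated).

    Returns one row per variable: group mean +/- SD, complete-case n per
    group, test used, p-value, and a significance asterisk at `alpha`. Sex
    is tested as a 2x2 nominal table. The report also carries the total
    number of tests run (no multiplicity correction is applied).
    """
    outcome_col = {"histopathological": "perforated", "surgical": "complicated"}
    if outcome not in outcome_col:
        raise ValidationError(f"unknown outcome {outcome!r}")
    y = cohort[outcome_col[outcome]].astype(int)
    if variables is None:
        skip = {"id", "sex", "histopath", "surgical_stage",
                "perforated", "complicated"}
        variables = [c for c in cohort.columns
                     if c not in skip and pd.api.types.is_numeric_dtype(cohort[c])]
    rows = []
    if "sex" in cohort.columns:
        tab = pd.crosstab(y, cohort["sex"]).reindex(
            index=[1, 0], fill_value=0).to_numpy()
        try:
            res = compare_categorical(tab)
            rows.append({"variable": "sex", "test": res.test_name,
                         "group_pos": "", "group_neg": "",
                         "n_pos": res.n_used[0], "n_neg": res.n_used[1],
                         "p_value": res.p_value})
        except DegenerateDataError as exc:
            logger.warning("sex comparison skipped: %s", exc)
    for var in variables:
        pos = cohort.loc[y == 1, var]
        neg = cohort.loc[y == 0, var]
        try:
            res = compare_continuous(pos, neg)
        except DegenerateDataError as exc:
            logger.warning("%s skipped: %s", var, exc)
            continue
        s1, s0 = res.group_summaries
        rows.append({
            "variable": var, "test": res.test_name,
            "group_pos": f"{s1['mean']:.2f} ± {s1['sd']:.2f}",
            "group_neg": f"{s0['mean']:.2f} ± {s0['sd']:.2f}",
            "n_pos": res.n_used[0], "n_neg": res.n_used[1],
            "p_value": res.p_value,
        })
    report = pd.DataFrame(rows)
    report["significant"] = np.where(report["p_value"] < alpha, "*", "")
    report.attrs["n_tests"] = len(report)
    report.attrs["outcome"] = outcome
    return report
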