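"""ROC curves, AUC inference, Youden-optimal cutoffs and 2x2 diagnostics.

The empirical ROC is evaluated over all distinct score thresholds with
positivity oriented as higher score = disease. The trapezoidal AUC then
equals the Mann-Whitney U statistic divided by n_pos * n_neg (ties counted
one half) — a property the test suite checks against a brute-force
pair-counting oracle. AUC confidence intervals and the p-value against
chance use the Hanley-McNeil normal approximation

    SE^2 = [A(1-A) + (n_pos-1)(Q1 - A^2) + (n_neg-1)(Q2 - A^2)] / (n_pos n_neg)
    Q1 = A/(2-A),  Q2 = 2A^2/(1+A)

(DeLong's variance is available behind a flag). Cutoff performance reports
sensitivity, specificity, PPV, NPV, the Youden index J = Se + Sp - 100, and
the odds ratio with a Woolf log-method CI and Fisher-exact p-value. A zero
cell yields OR = +inf with a one-sided CI unless the Haldane-Anscombe 0.5
correction is enabled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .exceptions import DegenerateDataError, ValidationError
from .published import PUBLISHED_CUTOFFS

__all__ = [
    "RocResult",
    "TwoByTwo",
    "CutoffPerformance",
    "roc_curve",
    "auc_inference",
    "youden_optimal_cutoff",
    "performance_at_cutoff",
    "CutoffClassifier",
    "evaluate_indices",
]

_Z975 = float(stats.norm.ppf(0.975))


@dataclass
class RocResult:
    """Empirical ROC with Hanley-McNeil inference."""

    thresholds: np.ndarray   # descending; leading +inf anchors (0, 0)
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    p_vs_chance: float
    n_pos: int
    n_neg: int


@dataclass
class TwoByTwo:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])


@dataclass
class CutoffPerformance:
    """Diagnostic metrics at one cutoff (percent scale)."""

    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    youden: float
    odds_ratio: float
    or_ci: tuple[float, float]
    or_p: float
    table: TwoByTwo
    degenerate: bool = False


def _clean_scores(scores, labels):
    s = np.asarray(pd.to_numeric(pd.Series(scores), errors="coerce"), dtype=float)
    y = np.asarray(labels).astype(float)
    keep = np.isfinite(s) & np.isfinite(y)
    s, y = s[keep], y[keep].astype(int)
    if not np.isin(y, (0, 1)).all():
        raise ValidationError("labels must be binary 0/1")
    return s, y


def roc_curve(scores, labels, *, ci_method: str = "hanley-mcneil") -> RocResult:
    """Empirical ROC of a score against a binary outcome.

    Missing scores are dropped; requires at least one case in each class.
    """
    s, y = _clean_scores(scores, labels)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateDataError("need at least one positive and one "
                                  "negative with non-missing scores")
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    a = float(_trapezoid_auc(fpr, tpr))
    ci, p = auc_inference(a, n_pos, n_neg,
                          scores=s, labels=y, method=ci_method)
    return RocResult(thresholds=thr, tpr=tpr, fpr=fpr, auc=a,
                     auc_ci=ci, p_vs_chance=p, n_pos=n_pos, n_neg=n_neg)


def _delong_se(scores, labels):
    """DeLong variance of the AUC via placement values."""
    s, y = np.asarray(scores, float), np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    return float(np.sqrt(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n))


def auc_inference(auc: float, n_pos: int, n_neg: int, *,
                  scores=None, labels=None,
                  method: str = "hanley-mcneil"):
    """95% CI (clipped to [0, 1]) and two-sided p-value against AUC = 0.5."""
    if not 0 <= auc <= 1:
        raise ValidationError("AUC must lie in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValidationError("group sizes must be >= 1")
    if method == "hanley-mcneil":
        a = auc
        q1, q2 = a / (2 - a), 2 * a * a / (1 + a)
        var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a)
               + (n_neg - 1) * (q2 - a * a)) / (n_pos * n_neg)
        se = float(np.sqrt(max(var, 0.0)))
    elif method == "delong":
        if scores is None or labels is None:
            raise ValidationError("DeLong inference needs the raw scores")
        se = _delong_se(scores, labels)
    else:
        raise ValidationError(f"unknown CI method {method!r}")
    lo = max(0.0, auc - _Z975 * se)
    hi = min(1.0, auc + _Z975 * se)
    if se == 0:
        p = 0.0 if auc != 0.5 else 1.0
    else:
        p = float(2 * stats.norm.sf(abs(auc - 0.5) / se))
    return (lo, hi), min(p, 1.0)


def youden_optimal_cutoff(roc: RocResult) -> float:
    """Observed score value maximising J = Se + Sp - 100.

    Ties break toward higher sensitivity, then toward the lower threshold,
    so a perfectly separating problem returns the smallest score that still
    achieves J = 100.
    """
    # The stored curve point i classifies positive iff score >= thresholds[i];
    # under the package's strict ">" convention the same partition is produced
    # by the next (lower) distinct score, so cutoffs shift by one position.
    # The all-positive endpoint has no observed-score strict cutoff.
    j = roc.tpr[:-1] - roc.fpr[:-1]
    tpr = roc.tpr[:-1]
    cuts = roc.thresholds[1:]
    best_j = j.max()
    at_best = np.flatnonzero(np.isclose(j, best_j, atol=1e-12))
    best_tpr = tpr[at_best].max()
    at_best = at_best[np.isclose(tpr[at_best], best_tpr, atol=1e-12)]
    return float(cuts[at_best].min())


def performance_at_cutoff(scores, labels, cutoff: float, *,
                          haldane: bool = False,
                          strict: bool = True) -> CutoffPerformance:
    """Dichotomize at `cutoff` (positive iff score > cutoff) and report the
    full 2x2-derived metric set.

    With a zero cell the odds ratio is +inf (one-sided CI: the lower bound
    uses 0.5-corrected cells); ``haldane=True`` applies the
    Haldane-Anscombe 0.5 correction throughout instead. A cutoff that
    empties a predicted or true class yields metrics flagged degenerate.
    """
    if not np.isfinite(cutoff):
        raise ValidationError("cutoff must be finite")
    s, y = _clean_scores(scores, labels)
    pred = s > cutoff if strict else s >= cutoff
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    table = TwoByTwo(tp, fp, fn, tn)
    if table.total == 0 or (tp + fn) == 0 or (fp + tn) == 0:
        raise DegenerateDataError("a true class is empty after cleaning")

    def pct(num, den):
        return 100.0 * num / den if den > 0 else float("nan")

    se = pct(tp, tp + fn)
    sp = pct(tn, tn + fp)
    ppv = pct(tp, tp + fp)
    npv = pct(tn, tn + fn)
    youden = se + sp - 100.0

    degenerate = (tp + fp) == 0 or (fn + tn) == 0
    cells = np.array([tp, fp, fn, tn], dtype=float)
    if haldane:
        cells = cells + 0.5
    a, b, c, d = cells
    if degenerate:
        odds, ci = float("nan"), (float("nan"), float("nan"))
    elif min(cells) > 0:
        odds = (a * d) / (b * c)
        w = np.sqrt((1 / cells).sum())
        ci = (float(np.exp(np.log(odds) - _Z975 * w)),
              float(np.exp(np.log(odds) + _Z975 * w)))
    else:
        # zero cell, no correction requested: +inf point estimate,
        # one-sided lower bound from the corrected table
        odds = float("inf") if b * c == 0 else 0.0
        ac = cells + 0.5
        orc = (ac[0] * ac[3]) / (ac[1] * ac[2])
        w = np.sqrt((1 / ac).sum())
        lo = float(np.exp(np.log(orc) - _Z975 * w))
        ci = (lo, float("inf")) if odds == float("inf") else (0.0, lo)
    or_p = float(stats.fisher_exact(table.as_array()).pvalue)
    return CutoffPerformance(cutoff=float(cutoff), sensitivity=se,
                             specificity=sp, ppv=ppv, npv=npv, youden=youden,
                             odds_ratio=odds, or_ci=ci, or_p=or_p,
                             table=table, degenerate=degenerate)


class CutoffClassifier(BaseEstimator, ClassifierMixin):
    """Single-score threshold classifier with Youden-optimal fitting.

    Parameters
    ----------
    cutoff : float or None
        Fixed decision threshold; None (default) fits the Youden-optimal
        cutoff from the training data.
    strict : bool, default True
        Positive iff score > cutoff (ties negative).

    Attributes
    ----------
    cutoff_ : float
    roc_ : RocResult            (when fitted from data)
    performance_ : CutoffPerformance  on the training data at ``cutoff_``.
    """

    def __init__(self, cutoff: float | None = None, strict: bool = True):
        self.cutoff = cutoff
        self.strict = strict

    @staticmethod
    def _scores(X) -> np.ndarray:
        a = np.asarray(X, dtype=float)
        if a.ndim == 2:
            if a.shape[1] != 1:
                raise ValidationError("CutoffClassifier expects a single score "
                                      "column")
            a = a[:, 0]
        return a

    def fit(self, X, y):
        s = self._scores(X)
        self.classes_ = np.array([0, 1])
        self.roc_ = roc_curve(s, y)
        self.cutoff_ = (float(self.cutoff) if self.cutoff is not None
                        else youden_optimal_cutoff(self.roc_))
        self.performance_ = performance_at_cutoff(s, y, self.cutoff_,
                                                  strict=self.strict)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        s = self._scores(X)
        pred = s > self.cutoff_ if self.strict else s >= self.cutoff_
        return pred.astype(int)

    def decision_function(self, X):
        return self._scores(X) - self.cutoff_


def evaluate_indices(cohort: pd.DataFrame, outcome: str,
                     index_cols: list[str], *,
                     cutoff_mode: str = "youden",
                     units_policy: str = "count") -> pd.DataFrame:
    """Per-index diagnostic evaluation table (ROC + cutoff performance).

    Parameters
    ----------
    cohort : DataFrame
        Must contain the index score columns and the binary outcome column
        ("perforated" or "complicated").
    outcome : {"histopathological", "surgical"}
    cutoff_mode : {"youden", "published"}
        Fit the Youden-optimal cutoff per index, or apply the published
        fixed cutoffs for the chosen classification.

    Returns one row per index: AUC with CI and p, the cutoff used, Se, Sp,
    PPV, NPV, Youden J, OR with CI and Fisher p, and n_used per class.
    """
    outcome_col = {"histopathological": "perforated", "surgical": "complicated"}
    if outcome not in outcome_col:
        raise ValidationError(f"unknown outcome {outcome!r}")
    if cutoff_mode not in ("youden", "published"):
        raise ValidationError(f"unknown cutoff mode {cutoff_mode!r}")
    y = cohort[outcome_col[outcome]]
    rows = []
    for name in index_cols:
        roc = roc_curve(cohort[name], y)
        if cutoff_mode == "youden":
            cut = youden_optimal_cutoff(roc)
        else:
            cut = PUBLISHED_CUTOFFS[outcome][name.lower()]
        perf = performance_at_cutoff(cohort[name], y, cut)
        rows.append({
            "index": name, "auc": roc.auc,
            "auc_ci_low": roc.auc_ci[0], "auc_ci_high": roc.auc_ci[1],
            "auc_p": roc.p_vs_chance, "cutoff": cut,
            "sensitivity": perf.sensitivity, "specificity": perf.specificity,
            "ppv": perf.ppv, "npv": perf.npv, "youden": perf.youden,
            "odds_ratio": perf.odds_ratio,
            "or_ci_low": perf.or_ci[0], "or_ci_high": perf.or_ci[1],
            "or_p": perf.or_p,
            "n_pos": roc.n_pos, "n_neg": roc.n_neg,
        })
    out = pd.DataFrame(rows)
    out.attrs["outcome"] = outcome
    out.attrs["cutoff_mode"] = cutoff_mode
    out.attrs["units_policy"] = units_policy
    return out


def render_p(p: float) -> str:
    """Report-layer p-value format: values below 5e-4 print as '<=0.0005'."""
    return "≤0.0005" if p < 5e-4 else f"{p:.4f}"
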