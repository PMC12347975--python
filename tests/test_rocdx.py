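"""ROC construction, AUC inference, Youden cutoffs, 2x2 diagnostics."""

import numpy as np
import pytest
from scipy import stats
from sklearn.base import clone

from metinflam import (CutoffClassifier, DegenerateDataError, auc_inference,
                       performance_at_cutoff, roc_curve,
                       youden_optimal_cutoff)


def pair_counting_auc(scores, labels):
    """Brute-force probability that a positive outscores a negative (ties 1/2)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestRocCurve:
    def test_perfect_separation(self):
        r = roc_curve([1, 2, 3, -1, 0], [1, 1, 1, 0, 0])
        assert r.auc == 1.0
        assert r.n_pos == 3 and r.n_neg == 2

    def test_chance_limit_on_permuted_labels(self, rng):
        s = rng.normal(size=4000)
        y = rng.permutation(np.repeat([0, 1], 2000))
        r = roc_curve(s, y)
        assert abs(r.auc - 0.5) < 0.03
        assert r.auc_ci[0] < 0.5 < r.auc_ci[1]

    def test_trapezoid_equals_mann_whitney_u(self, rng):
        for _ in range(200):
            n1 = rng.integers(2, 30)
            n0 = rng.integers(2, 30)
            s = rng.integers(0, 10, size=n1 + n0).astype(float)  # many ties
            y = np.r_[np.ones(n1, int), np.zeros(n0, int)]
            r = roc_curve(s, y)
            u = stats.mannwhitneyu(s[y == 1], s[y == 0],
                                   alternative="two-sided").statistic
            assert r.auc == pytest.approx(u / (n1 * n0), abs=1e-12)
            assert r.auc == pytest.approx(pair_counting_auc(s, y), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        s = rng.normal(size=200)
        y = (rng.random(200) < 0.3).astype(int)
        base = roc_curve(s, y).auc
        for f in (np.exp, np.tanh, lambda x: x ** 3 + 5 * x):
            assert roc_curve(f(s), y).auc == pytest.approx(base, abs=1e-12)

    def test_curve_monotone_endpoints(self, rng):
        r = roc_curve(rng.normal(size=100), rng.integers(0, 2, 100))
        assert (np.diff(r.tpr) >= 0).all() and (np.diff(r.fpr) >= 0).all()
        assert (r.tpr[0], r.fpr[0]) == (0, 0)
        assert (r.tpr[-1], r.fpr[-1]) == (1, 1)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateDataError):
            roc_curve([1.0, 2.0], [1, 1])


class TestAucInference:
    def test_null_center_p_one(self):
        _, p = auc_inference(0.5, 20, 30)
        assert p == 1.0

    def test_reported_significance_at_study_sizes(self):
        # AUC 0.742 with 19 complete perforated vs 177 non-perforated
        (lo, hi), p = auc_inference(0.742, 19, 177)
        assert p <= 0.0005
        assert lo < 0.742 < hi <= 1.0

    def test_se_close_to_bootstrap(self, rng):
        """Hanley-McNeil SE vs a stratified bootstrap at moderate AUC."""
        n1, n0 = 100, 100
        s = np.r_[rng.normal(0.5, 1, n1), rng.normal(0, 1, n0)]
        y = np.r_[np.ones(n1, int), np.zeros(n0, int)]
        a = roc_curve(s, y).auc
        q1, q2 = a / (2 - a), 2 * a * a / (1 + a)
        se = np.sqrt((a * (1 - a) + (n1 - 1) * (q1 - a * a)
                      + (n0 - 1) * (q2 - a * a)) / (n1 * n0))
        boot = []
        for _ in range(10_000):
            ip = rng.integers(0, n1, n1)
            iq = rng.integers(0, n0, n0)
            sb = np.r_[s[:n1][ip], s[n1:][iq]]
            boot.append(roc_curve(sb, y).auc)
        assert se == pytest.approx(np.std(boot, ddof=1), rel=0.15)

    def test_delong_flag(self, rng):
        s = rng.normal(size=100)
        y = np.r_[np.ones(40, int), np.zeros(60, int)]
        r = roc_curve(s, y, ci_method="delong")
        assert r.auc_ci[0] < r.auc < r.auc_ci[1]


class TestYoudenCutoff:
    def test_matches_exhaustive_scan(self, rng):
        for _ in range(100):
            n = rng.integers(8, 40)
            s = np.round(rng.normal(size=n), 1)
            y = (rng.random(n) < 0.4).astype(int)
            if y.sum() in (0, n):
                continue
            r = roc_curve(s, y)
            cut = youden_optimal_cutoff(r)
            best = max(
                100 * np.mean(s[y == 1] > c) + 100 * np.mean(s[y == 0] <= c)
                - 100 for c in np.unique(s))
            j = (100 * np.mean(s[y == 1] > cut)
                 + 100 * np.mean(s[y == 0] <= cut) - 100)
            assert j == pytest.approx(best, abs=1e-9)
            assert cut in s

    def test_perfect_separation_gap(self):
        r = roc_curve([10, 11, 12, 1, 2], [1, 1, 1, 0, 0])
        cut = youden_optimal_cutoff(r)
        assert 2 <= cut < 10  # any cutoff in the gap attains J = 100
        perf = performance_at_cutoff([10, 11, 12, 1, 2], [1, 1, 1, 0, 0], cut)
        assert perf.youden == pytest.approx(100.0)

    def test_label_flip_symmetry(self, rng):
        s = rng.normal(size=60)
        y = (rng.random(60) < 0.5).astype(int)
        r1 = roc_curve(s, y)
        r2 = roc_curve(-s, 1 - y)
        j1 = (r1.tpr - r1.fpr).max()
        j2 = (r2.tpr - r2.fpr).max()
        assert j1 == pytest.approx(j2, abs=1e-12)


class TestCutoffPerformance:
    def test_constructed_table_metrics(self, rng):
        # build scores realizing tp=18, fn=1, fp=120, tn=57 at cutoff 0
        s = np.r_[np.ones(18), -np.ones(1), np.ones(120), -np.ones(57)]
        y = np.r_[np.ones(19, int), np.zeros(177, int)]
        perf = performance_at_cutoff(s, y, 0.0)
        assert (perf.table.tp, perf.table.fn) == (18, 1)
        assert perf.sensitivity == pytest.approx(100 * 18 / 19, abs=5e-3)
        assert perf.sensitivity == pytest.approx(94.74, abs=0.01)
        assert perf.youden == pytest.approx(
            perf.sensitivity + perf.specificity - 100, abs=1e-12)
        assert perf.odds_ratio == pytest.approx(18 * 57 / (120 * 1))
        # Woolf CI brackets the estimate; Fisher p from the same table
        assert perf.or_ci[0] < perf.odds_ratio < perf.or_ci[1]
        assert perf.or_p == pytest.approx(
            stats.fisher_exact([[18, 1], [120, 57]]).pvalue)

    def test_all_negative_predictions_flagged(self):
        perf = performance_at_cutoff([1, 2, 3, 4], [1, 1, 0, 0], 10.0)
        assert perf.sensitivity == 0.0 and perf.specificity == 100.0
        assert perf.degenerate and np.isnan(perf.odds_ratio)

    def test_zero_cell_gives_infinite_or(self):
        perf = performance_at_cutoff([5, 6, 1, 2, 7], [1, 1, 0, 0, 0], 4.0)
        assert perf.odds_ratio == np.inf
        assert perf.or_ci[1] == np.inf and perf.or_ci[0] > 0
        corrected = performance_at_cutoff([5, 6, 1, 2, 7], [1, 1, 0, 0, 0],
                                          4.0, haldane=True)
        assert np.isfinite(corrected.odds_ratio)

    def test_or_exceeds_one_iff_diagonal_dominates(self, rng):
        for _ in range(50):
            s = rng.normal(size=30)
            y = (rng.random(30) < 0.5).astype(int)
            if y.sum() in (0, 30):
                continue
            perf = performance_at_cutoff(s, y, float(np.median(s)))
            t = perf.table
            if min(t.tp, t.fp, t.fn, t.tn) > 0:
                assert (perf.odds_ratio > 1) == (t.tp * t.tn > t.fp * t.fn)


class TestCutoffClassifier:
    def test_fit_predict_roundtrip(self, rng):
        s = np.r_[rng.normal(2, 1, 50), rng.normal(0, 1, 50)]
        y = np.r_[np.ones(50, int), np.zeros(50, int)]
        clf = CutoffClassifier().fit(s, y)
        assert clf.cutoff_ == youden_optimal_cutoff(clf.roc_)
        pred = clf.predict(s)
        assert pred.mean() > 0.2 and clf.score(s, y) > 0.7
        fixed = clone(clf).set_params(cutoff=1.0).fit(s, y)
        assert fixed.cutoff_ == 1.0
        assert ((s > 1.0).astype(int) == fixed.predict(s)).all()

    def test_index_evaluation_separates_default_cohort(self, default_cohort):
        from metinflam import IndexCalculator, evaluate_indices
        import pandas as pd
        scores = IndexCalculator().fit(default_cohort).transform(default_cohort)
        scored = pd.concat([default_cohort, scores], axis=1)
        table = evaluate_indices(scored, "histopathological",
                                 ["imi", "misi"], cutoff_mode="published")
        assert (table["auc"] > 0.5).all()
        assert (table["auc_p"] < 0.05).all()
        assert (table["n_pos"] == 21).all()
        assert np.allclose(table["youden"],
                           table["sensitivity"] + table["specificity"] - 100)
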