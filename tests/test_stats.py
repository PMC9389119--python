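"""ROC/Youden, DeLong, screening, logistic and kappa against oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from lnfusion.stats import (
    auc_ci_delong,
    cohens_kappa,
    fit_logistic,
    roc_points,
    univariate_screen,
    youden_cutoff,
)


def mann_whitney_auc(scores, labels):
    """Pairwise comparison probability P(pos > neg) + 0.5 P(tie)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        curve = roc_points([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert curve.auc == pytest.approx(1.0)

    def test_infinite_scores_rank_like_extremes(self):
        scores = [1.0, 2.0, np.inf, np.inf, 3.0, -np.inf]
        labels = [0, 0, 1, 1, 1, 0]
        curve = roc_points(scores, labels)
        assert curve.auc == pytest.approx(mann_whitney_auc(scores, labels))
        # midpoint thresholds must stay finite so a usable cutoff exists
        assert np.isfinite(curve.thresholds[1:-1]).all()

    def test_nan_scores_rejected(self):
        with pytest.raises(ValueError):
            roc_points([1.0, np.nan, 2.0, 3.0], [0, 1, 0, 1])

    def test_identical_scores(self):
        curve = roc_points([5.0] * 10, [0, 1] * 5)
        assert curve.auc == pytest.approx(0.5)

    def test_auc_equals_mann_whitney_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 30))
            scores = rng.integers(0, 8, size=n).astype(float)  # forces ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            got = roc_points(scores, labels).auc
            assert got == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-10)
            assert got == pytest.approx(roc_auc_score(labels, scores), abs=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_points([1, 2, 3], [1, 1, 1])


class TestYouden:
    def test_separated_grades(self):
        curve = roc_points([3, 4, 5, 1, 2], [1, 1, 1, 0, 0])
        cut = youden_cutoff(curve)
        assert cut.cutoff == pytest.approx(2.5)
        assert cut.youden_j == pytest.approx(1.0)

    def test_no_information(self):
        curve = roc_points([2.0] * 6, [0, 1] * 3)
        assert youden_cutoff(curve).youden_j == pytest.approx(0.0)

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(50):
            scores = rng.normal(size=30)
            labels = rng.integers(0, 2, size=30)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            cut = youden_cutoff(roc_points(scores, labels))
            # brute force over a fine threshold grid
            best_j = -2.0
            for t in np.sort(np.concatenate([scores - 1e-9, scores + 1e-9,
                                             [-1e9, 1e9]])):
                call = scores > t
                sens = (call & (labels == 1)).sum() / (labels == 1).sum()
                spec = (~call & (labels == 0)).sum() / (labels == 0).sum()
                best_j = max(best_j, sens + spec - 1)
            assert cut.youden_j == pytest.approx(best_j, abs=1e-10)

    def test_sens_spec_consistent_at_cutoff(self, rng):
        scores = rng.normal(size=40)
        labels = (rng.random(40) < 0.5).astype(int)
        labels[:2] = [0, 1]
        cut = youden_cutoff(roc_points(scores, labels))
        call = scores > cut.cutoff
        assert cut.sensitivity == pytest.approx(
            (call & (labels == 1)).sum() / labels.sum())
        assert cut.specificity == pytest.approx(
            (~call & (labels == 0)).sum() / (labels == 0).sum())


class TestDeLong:
    def test_perfect_auc_upper_bound(self):
        scores = np.concatenate([np.zeros(50), np.ones(50)])
        labels = np.concatenate([np.zeros(50), np.ones(50)]).astype(int)
        lo, hi = auc_ci_delong(scores, labels)
        assert hi == 1.0 and lo == 1.0  # degenerate variance -> point interval

    def test_label_swap_symmetry(self, rng):
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        lo, hi = auc_ci_delong(scores, labels)
        lo2, hi2 = auc_ci_delong(scores, 1 - labels)
        assert lo2 == pytest.approx(1 - hi, abs=1e-12)
        assert hi2 == pytest.approx(1 - lo, abs=1e-12)

    def test_ci_contains_auc_and_overlaps_bootstrap(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 40), rng.normal(1, 1, 40)])
        labels = np.concatenate([np.zeros(40), np.ones(40)]).astype(int)
        lo, hi = auc_ci_delong(scores, labels)
        auc = roc_points(scores, labels).auc
        assert lo <= auc <= hi
        # bootstrap oracle
        boots = []
        for _ in range(2000):
            idx = rng.integers(0, 80, size=80)
            yb = labels[idx]
            if yb.min() == yb.max():
                continue
            boots.append(mann_whitney_auc(scores[idx], yb))
        blo, bhi = np.percentile(boots, [2.5, 97.5])
        # intervals estimated two ways must overlap substantially
        assert max(lo, blo) < min(hi, bhi)
        assert abs(lo - blo) < 0.08 and abs(hi - bhi) < 0.08


def fisher_oracle(table):
    """Two-sided Fisher p by enumerating the hypergeometric support."""
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d
    pmf = sps.hypergeom(n, r1, c1)
    p_obs = pmf.pmf(a)
    return sum(pmf.pmf(k) for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
               if pmf.pmf(k) <= p_obs * (1 + 1e-9))


class TestUnivariateScreen:
    def test_perfect_association(self):
        calls = [1] * 50 + [0] * 50
        labels = [1] * 50 + [0] * 50
        assert univariate_screen(calls, labels) < 1e-10

    def test_identical_rows_fisher_p1(self):
        calls = [1, 1, 0, 0]
        labels = [1, 0, 1, 0]
        assert univariate_screen(calls, labels) == pytest.approx(1.0)

    def test_small_tables_match_fisher_enumeration(self, rng):
        for _ in range(30):
            calls = rng.integers(0, 2, size=12)
            labels = rng.integers(0, 2, size=12)
            if calls.min() == calls.max() or labels.min() == labels.max():
                continue
            table = [
                [int(((calls == 1) & (labels == 1)).sum()),
                 int(((calls == 1) & (labels == 0)).sum())],
                [int(((calls == 0) & (labels == 1)).sum()),
                 int(((calls == 0) & (labels == 0)).sum())],
            ]
            expected = sps.contingency.expected_freq(np.array(table))
            if (expected >= 5).all():
                continue  # chi-square branch, not Fisher
            assert univariate_screen(calls, labels) == pytest.approx(
                fisher_oracle(table), abs=1e-9)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            univariate_screen([1, 1, 1, 1], [1, 0, 1, 0])


class TestLogistic:
    def test_single_binary_predictor_recovers_log_odds_ratio(self, rng):
        x = rng.integers(0, 2, size=400)
        p = np.where(x == 1, 0.7, 0.3)
        y = (rng.random(400) < p).astype(int)
        a = ((x == 1) & (y == 1)).sum()
        b = ((x == 1) & (y == 0)).sum()
        c = ((x == 0) & (y == 1)).sum()
        d = ((x == 0) & (y == 0)).sum()
        model = fit_logistic(pd.DataFrame({"x": x}), y, screen=False)
        assert model.converged
        assert model.params["x"] == pytest.approx(np.log(a * d / (b * c)), abs=1e-6)

    def test_intercept_only_is_logit_prevalence(self):
        y = np.array([1] * 30 + [0] * 70)
        model = fit_logistic(pd.DataFrame(index=range(100)), y, screen=False)
        assert model.params["const"] == pytest.approx(np.log(0.3 / 0.7), abs=1e-8)

    def test_constant_predictor_rejected(self):
        y = np.array([0, 1] * 10)
        with pytest.raises(ValueError):
            fit_logistic(pd.DataFrame({"x": np.ones(20)}), y, screen=False)

    def test_separation_is_flagged(self):
        x = np.array([0] * 10 + [1] * 10)
        y = x.copy()
        model = fit_logistic(pd.DataFrame({"x": x}), y, screen=False)
        assert model.separation or not model.converged

    def test_recovers_generating_coefficients(self, rng):
        n = 2000
        x1 = rng.integers(0, 2, size=n)
        x2 = rng.integers(0, 2, size=n)
        eta = -0.5 + 1.2 * x1 + 0.8 * x2
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        model = fit_logistic(pd.DataFrame({"x1": x1, "x2": x2}), y, screen=False)
        for name, true in [("const", -0.5), ("x1", 1.2), ("x2", 0.8)]:
            assert abs(model.params[name] - true) < 3 * model.bse[name]


class TestKappa:
    def test_identical_ratings(self):
        r = [1, 2, 3, 4, 5] * 10
        assert cohens_kappa(r, r).kappa == pytest.approx(1.0)

    def test_chance_agreement_zero(self):
        a = [1, 1, 2, 2]
        b = [1, 2, 1, 2]
        res = cohens_kappa(a, b)
        assert res.observed_agreement == pytest.approx(res.expected_agreement)
        assert res.kappa == pytest.approx(0.0)

    def test_matches_direct_formula_and_sklearn(self, rng):
        a = rng.integers(1, 6, size=50)
        b = rng.integers(1, 6, size=50)
        res = cohens_kappa(a, b, categories=range(1, 6))
        # direct contingency-table construction
        table = np.zeros((5, 5))
        for x, y in zip(a, b):
            table[x - 1, y - 1] += 1
        po = np.trace(table) / 50
        pe = (table.sum(1) * table.sum(0)).sum() / 50**2
        assert res.kappa == pytest.approx((po - pe) / (1 - pe), abs=1e-12)
        assert res.kappa == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    def test_relabeling_invariance(self, rng):
        a = rng.integers(1, 6, size=40)
        b = rng.integers(1, 6, size=40)
        perm = dict(zip(range(1, 6), rng.permutation(range(1, 6))))
        a2 = np.array([perm[v] for v in a])
        b2 = np.array([perm[v] for v in b])
        assert cohens_kappa(a2, b2).kappa == pytest.approx(
            cohens_kappa(a, b).kappa, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cohens_kappa([], [])
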