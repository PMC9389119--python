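"""Statistical procedures for diagnostic-marker evaluation.

ROC analysis with Youden-index cutoff selection, DeLong confidence
intervals for the AUC, chi-square/Fisher univariate screening of
dichotomized predictors, multivariable logistic regression, and Cohen's
kappa for rater agreement.

Conventions: the positive call is *strictly greater than* the threshold
everywhere, and Youden ties are broken toward higher specificity (then
lower cutoff), reflecting the clinical emphasis on reducing false
positives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "RocCurve",
    "CutoffResult",
    "LogisticModel",
    "KappaResult",
    "roc_points",
    "auc_ci_delong",
    "youden_cutoff",
    "univariate_screen",
    "fit_logistic",
    "cohens_kappa",
]


@dataclass(frozen=True)
class RocCurve:
    """ROC curve: thresholds with the (sens, 1-spec) they induce, plus AUC."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    one_minus_specificity: np.ndarray
    auc: float
    auc_ci95: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must be in [0,1]")


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    youden_j: float
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        if abs(self.youden_j - (self.sensitivity + self.specificity - 1.0)) > 1e-12:
            raise ValueError("youden_j must equal sens + spec - 1")


@dataclass(frozen=True)
class LogisticModel:
    params: pd.Series
    pvalues: pd.Series
    converged: bool
    separation: bool = False
    bse: pd.Series | None = field(default=None, repr=False)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    observed_agreement: float
    expected_agreement: float


def _check_binary_labels(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    return y


def roc_points(scores, labels) -> RocCurve:
    """ROC curve over thresholds at midpoints between adjacent distinct scores.

    A node is called positive when its score is strictly greater than the
    threshold; −∞/+∞ anchors give the all-positive and all-negative corners.
    The AUC is the trapezoidal area, which equals the Mann–Whitney
    probability P(score_pos > score_neg) + ½P(tie).
    """
    s = np.asarray(scores, dtype=float)
    y = _check_binary_labels(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if np.isnan(s).any():
        raise ValueError("scores must not contain NaN")
    # ±inf sentinels (e.g. a ratio with an empty denominator band) are valid
    # extreme ranks: replace by finite values one unit past the extremes so
    # midpoint thresholds stay finite; AUC is rank-based and unchanged
    if np.isinf(s).any():
        finite = s[np.isfinite(s)]
        top = finite.max() + 1.0 if finite.size else 1.0
        bot = finite.min() - 1.0 if finite.size else -1.0
        s = np.where(s == np.inf, top, np.where(s == -np.inf, bot, s))
    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    sens = np.empty(thresholds.size)
    fpr = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        call = s > t
        sens[i] = np.count_nonzero(call & (y == 1)) / n_pos
        fpr[i] = np.count_nonzero(call & (y == 0)) / n_neg
    # integrate along the ROC staircase: increasing FPR, then increasing sens
    order = np.lexsort((sens, fpr))
    auc = float(np.trapezoid(sens[order], fpr[order]))
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        one_minus_specificity=fpr,
        auc=auc,
    )


def _delong_structural_components(scores: np.ndarray, labels: np.ndarray):
    """Midrank-based placement values V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_ranks = sps.rankdata(np.concatenate([pos, neg]))
    pos_ranks = sps.rankdata(pos)
    neg_ranks = sps.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return v10, v01


def auc_ci_delong(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """DeLong normal-approximation CI for the AUC, truncated to [0, 1].

    Degenerate variance (perfect separation) collapses to a point interval.
    """
    s = np.asarray(scores, dtype=float)
    y = _check_binary_labels(labels)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 observations per class")
    v10, v01 = _delong_structural_components(s, y)
    auc = float(v10.mean())
    var = v10.var(ddof=1) / v10.size + v01.var(ddof=1) / v01.size
    if var <= 0:
        warnings.warn("degenerate DeLong variance; returning point interval")
        return (auc, auc)
    z = sps.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return (max(0.0, auc - half), min(1.0, auc + half))


def youden_cutoff(curve: RocCurve) -> CutoffResult:
    """Cutoff maximizing J = sens + spec − 1.

    Ties go to the point with higher specificity, then the lower cutoff;
    deterministic for any input curve.
    """
    spec = 1.0 - curve.one_minus_specificity
    j = curve.sensitivity + spec - 1.0
    best = None
    for i in range(len(j)):
        key = (round(j[i], 15), round(spec[i], 15), -curve.thresholds[i])
        if best is None or key > best[0]:
            best = (key, i)
    i = best[1]
    cut = float(curve.thresholds[i])
    return CutoffResult(
        cutoff=cut,
        youden_j=float(curve.sensitivity[i] + spec[i] - 1.0),
        sensitivity=float(curve.sensitivity[i]),
        specificity=float(spec[i]),
    )


def univariate_screen(calls, labels) -> float:
    """P-value for association between a dichotomized call and the truth.

    Chi-squared with continuity correction when every expected count in the
    2×2 table is ≥ 5, otherwise Fisher's exact test.
    """
    c = np.asarray(calls).astype(int)
    y = np.asarray(labels).astype(int)
    if c.shape != y.shape:
        raise ValueError("calls and labels must have equal length")
    table = np.array(
        [
            [np.count_nonzero((c == 1) & (y == 1)), np.count_nonzero((c == 1) & (y == 0))],
            [np.count_nonzero((c == 0) & (y == 1)), np.count_nonzero((c == 0) & (y == 0))],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate 2x2 table (empty margin)")
    expected = sps.contingency.expected_freq(table)
    if (expected >= 5).all():
        return float(sps.chi2_contingency(table, correction=True)[1])
    return float(sps.fisher_exact(table)[1])


def fit_logistic(
    predictors: pd.DataFrame,
    labels,
    entry_p: float = 0.05,
    screen: bool = True,
) -> LogisticModel:
    """Multivariable logistic regression on (typically dichotomized) predictors.

    Predictors failing the univariate screen at ``entry_p`` are dropped before
    the fit (disable with ``screen=False`` to force clinically important
    variables in).  Maximum likelihood via Newton iterations (IRLS),
    tolerance 1e-8, at most 100 iterations; complete separation and
    non-convergence are reported on the result, never silently ignored.
    """
    y = _check_binary_labels(labels)
    X = pd.DataFrame(predictors).astype(float)
    if X.shape[0] != y.size:
        raise ValueError("predictors and labels must have equal length")
    constant_cols = [c for c in X.columns if X[c].nunique() <= 1]
    if constant_cols:
        raise ValueError(f"constant predictors cannot be fit: {constant_cols}")
    if screen and X.shape[1] > 0:
        keep = []
        for c in X.columns:
            col = X[c]
            call = col if col.nunique() == 2 else (col > col.median()).astype(int)
            if univariate_screen(call.astype(int), y) < entry_p:
                keep.append(c)
        X = X[keep]
    Xc = sm.add_constant(X, has_constant="add")
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            res = sm.Logit(y, Xc).fit(method="newton", maxiter=100, tol=1e-8, disp=False)
            converged = bool(res.mle_retvals.get("converged", True))
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning,
                np.linalg.LinAlgError):  # singular Hessian (collinear calls)
            separation = True
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, Xc).fit(method="bfgs", maxiter=200, disp=False)
            converged = False
    return LogisticModel(
        params=res.params,
        pvalues=res.pvalues,
        converged=converged and not separation,
        separation=separation,
        bse=res.bse,
    )


def cohens_kappa(ratings_a, ratings_b, categories=None) -> KappaResult:
    """Unweighted Cohen's kappa between two paired rating series."""
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.size == 0 or a.shape != b.shape:
        raise ValueError("ratings must be non-empty and paired")
    cats = np.asarray(categories) if categories is not None else np.unique(
        np.concatenate([a, b])
    )
    idx = {c: i for i, c in enumerate(cats.tolist())}
    k = len(cats)
    table = np.zeros((k, k), dtype=float)
    for x, yv in zip(a.tolist(), b.tolist()):
        table[idx[x], idx[yv]] += 1
    n = table.sum()
    po = float(np.trace(table) / n)
    pe = float((table.sum(axis=1) * table.sum(axis=0)).sum() / n**2)
    kappa = 1.0 if pe == 1.0 else (po - pe) / (1.0 - pe)
    return KappaResult(kappa=float(kappa), observed_agreement=po, expected_agreement=pe)
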