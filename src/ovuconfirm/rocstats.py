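"""Empirical ROC curves, AUC inference, paired DeLong comparison and 2×2 diagnostics.

The ROC machinery is deliberately empirical (no binormal smoothing):

* :func:`roc_curve` sweeps thresholds placed at midpoints between adjacent
  distinct scores and integrates the curve by the trapezoidal rule; tied
  scores collapse to one threshold step so the AUC equals the
  Mann–Whitney / concordance form ``(concordant + ½·ties) / (n₊·n₋)``.
* :func:`auc_mann_whitney` computes that concordance form directly from the
  Mann–Whitney U statistic and serves as an independent cross-check.
* :func:`delong_compare` implements the DeLong–DeLong–Clarke-Pearson
  covariance estimate from placement values, giving a z-test for the
  difference of two correlated AUCs measured on the same samples and the
  95% CI attached to a single AUC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RocCurve",
    "AucComparison",
    "DiagnosticSummary",
    "roc_curve",
    "auc_mann_whitney",
    "delong_compare",
    "auc_ci_delong",
    "youden_optimal",
    "diagnostics_from_table",
]


@dataclass
class RocCurve:
    """An empirical ROC curve with its trapezoidal AUC and DeLong 95% CI."""

    thresholds: np.ndarray  # ascending; operating rule is score > threshold
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    auc_ci_95: tuple[float, float]
    n_pos: int
    n_neg: int


@dataclass
class AucComparison:
    """Paired difference of two AUCs on the same samples (DeLong z-test)."""

    auc_a: float
    auc_b: float
    auc_difference: float
    variance: float
    z: float
    p_value: float


@dataclass
class DiagnosticSummary:
    """Sensitivity/specificity/PPV/NPV from a 2×2 table; 0/0 cells are None."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]

    @property
    def undefined_fields(self) -> list[str]:
        return [
            name
            for name in ("sensitivity", "specificity", "ppv", "npv")
            if getattr(self, name) is None
        ]


def _validate_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be paired 1-d sequences")
    if y.all() or not y.any():
        raise ValueError("need at least one positive and one negative label")
    return s, y


def roc_curve(scores: Sequence[float], labels: Sequence[bool]) -> RocCurve:
    """Empirical ROC over all distinct score thresholds.

    Thresholds sit at midpoints between adjacent distinct scores (plus
    sentinels below the minimum and above the maximum), so the operating
    rule "positive iff score > threshold" is deterministic and invariant to
    monotone rescaling of scores up to threshold placement.
    """
    s, y = _validate_scores_labels(scores, labels)
    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([distinct[0] - 1.0], mids, [distinct[-1] + 1.0]))
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    sens = np.array([(s[y] > t).mean() for t in thresholds])
    spec = np.array([(s[~y] <= t).mean() for t in thresholds])
    # integrate TPR over FPR (trapezoid); the empirical curve is monotone in
    # both coordinates, so lexicographic (FPR, TPR) order recovers the path
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))
    auc = float(np.trapezoid(sens[order], fpr[order]))
    _, var = _delong_auc_variance(s, y)
    half = 1.959963984540054 * np.sqrt(var)
    return RocCurve(
        thresholds=thresholds,
        sensitivities=sens,
        specificities=spec,
        auc=auc,
        auc_ci_95=(auc - half, auc + half),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def auc_mann_whitney(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """AUC as the normalized Mann–Whitney U: (concordant + ½·tied)/(n₊·n₋)."""
    s, y = _validate_scores_labels(scores, labels)
    pos, neg = s[y], s[~y]
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u) / (len(pos) * len(neg))


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong placement values via midranks (handles ties)."""
    m, n = len(pos), len(neg)
    combined = np.concatenate([pos, neg])
    r_all = stats.rankdata(combined)  # midranks
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n  # per-positive placement
    v01 = 1.0 - (r_all[m:] - r_neg) / m  # per-negative placement
    auc = float(v10.mean())
    return v10, v01, auc


def _delong_auc_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    v10, v01, auc = _placements(scores[labels], scores[~labels])
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    return auc, float(var)


def auc_ci_delong(
    scores: Sequence[float], labels: Sequence[bool], level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """AUC with its DeLong asymptotic-normal confidence interval."""
    s, y = _validate_scores_labels(scores, labels)
    auc, var = _delong_auc_variance(s, y)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return auc, (auc - half, auc + half)


def delong_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[bool],
) -> AucComparison:
    """DeLong test for the difference of two correlated AUCs.

    Both score vectors must be measured on the same samples (identical
    labels); the covariance of the paired placement values yields the
    variance of the AUC difference and a two-tailed z-test.
    """
    sa, y = _validate_scores_labels(scores_a, labels)
    sb, y2 = _validate_scores_labels(scores_b, labels)
    if len(sa) != len(sb):
        raise ValueError("paired comparison needs equal-length score vectors")
    v10a, v01a, auc_a = _placements(sa[y], sa[~y])
    v10b, v01b, auc_b = _placements(sb[y], sb[~y])
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    var = max(float(var), 0.0)
    diff = auc_a - auc_b
    if var == 0.0:
        z = 0.0 if diff == 0.0 else np.inf * np.sign(diff)
    else:
        z = diff / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    if diff == 0.0:
        p = 1.0
    return AucComparison(
        auc_a=auc_a, auc_b=auc_b, auc_difference=diff, variance=var,
        z=float(z), p_value=p,
    )


def youden_optimal(roc: RocCurve) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity − 1.

    Ties in J are broken toward higher specificity (the more conservative
    operating point); a flat J = 0 curve returns the lowest threshold with a
    warning since no threshold discriminates.
    """
    j = roc.sensitivities + roc.specificities - 1.0
    best_j = j.max()
    if best_j <= 0:
        import warnings

        warnings.warn("ROC curve has no discriminating threshold (max J <= 0)")
        return float(roc.thresholds[0])
    candidates = np.flatnonzero(np.isclose(j, best_j))
    best = candidates[np.argmax(roc.specificities[candidates])]
    return float(roc.thresholds[best])


def diagnostics_from_table(a: int, b: int, c: int, d: int) -> DiagnosticSummary:
    """Sensitivity a/(a+c), specificity d/(b+d), PPV a/(a+b), NPV d/(c+d).

    Any 0/0 ratio is reported as None (undefined) rather than a degenerate
    1.0 or 0.0: a column or row with no observations carries no information
    about the corresponding rate.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("confusion counts must be non-negative")

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    return DiagnosticSummary(
        sensitivity=ratio(a, a + c),
        specificity=ratio(d, b + d),
        ppv=ratio(a, a + b),
        npv=ratio(d, c + d),
    )
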