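"""Platform agreement and analytical-validation statistics.

Covers the standard clinical-chemistry comparison toolbox for two assays
measuring the same analyte, plus the validation experiments run when a
serum immunoassay is repurposed for urine:

* Pearson correlation on log-transformed pairs (skewed hormone data);
* Bland–Altman bias, 95% limits of agreement and a proportional-bias slope;
* Passing–Bablok structural regression (rank-based, outlier-robust,
  no error-free-x assumption), with the classical rank-based CI;
* spike-recovery / dilution linearity;
* within- and between-run imprecision by one-way random-effects ANOVA;
* freeze-thaw stability as percent change from index aliquots;
* immunoassay cross-reactivity from spiked vs unspiked samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger("ovuconfirm")

__all__ = [
    "BlandAltmanResult",
    "PassingBablokResult",
    "RecoveryResult",
    "PrecisionResult",
    "StabilityResult",
    "CrossReactivityResult",
    "pearson_log",
    "bland_altman",
    "passing_bablok",
    "recovery_analysis",
    "precision_anova",
    "freeze_thaw_change",
    "cross_reactivity",
]


@dataclass
class BlandAltmanResult:
    mean_difference: float
    loa_lower: float
    loa_upper: float
    sd_differences: float
    proportional_bias_slope: float
    n: int


@dataclass
class PassingBablokResult:
    slope: float
    slope_ci_95: tuple[float, float]
    intercept: float
    intercept_ci_95: tuple[float, float]
    n_pairs: int


@dataclass
class RecoveryResult:
    expected: np.ndarray  # concentration per dilution level
    observed_mean: np.ndarray
    percent_recovery: np.ndarray
    recovery_sd: np.ndarray  # SD of per-replicate percent recovery
    linearity_r: float


@dataclass
class PrecisionResult:
    grand_mean: float
    within_run_cv: float  # percent
    between_run_cv: float  # percent
    ms_within: float
    ms_between: float


@dataclass
class StabilityResult:
    counts: np.ndarray  # freeze-thaw cycle counts, 0 first
    mean_percent_change: np.ndarray  # vs the count-0 (index) mean
    sd_percent_change: np.ndarray
    index_mean: float


@dataclass
class CrossReactivityResult:
    percent_cross_reactivity: float
    spiked_mean: float
    unspiked_mean: float
    spike_concentration: float


def pearson_log(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r and two-tailed p on natural-log-transformed pairs.

    Non-positive values cannot be log-transformed; those pairs are dropped
    with a logged count (r is base-invariant, natural log is used).
    """
    xa, ya = np.asarray(x, float), np.asarray(y, float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must be paired")
    ok = (xa > 0) & (ya > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("pearson_log: dropped %d non-positive pairs", n_dropped)
    if ok.sum() < 3:
        raise ValueError("need at least 3 positive pairs for correlation")
    r, p = stats.pearsonr(np.log(xa[ok]), np.log(ya[ok]))
    return float(r), float(p)


def bland_altman(x: Sequence[float], y: Sequence[float]) -> BlandAltmanResult:
    """Agreement of paired measurements: bias, 95% LoA and proportional bias.

    Differences are ``d = x − y`` and pairwise means ``m = (x + y)/2``;
    the limits of agreement are ``mean(d) ± 1.96·sd(d)`` and the
    proportional-bias slope is the least-squares slope of d on m (a nonzero
    slope means the discrepancy depends on concentration).
    """
    xa, ya = np.asarray(x, float), np.asarray(y, float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be paired 1-d sequences")
    if len(xa) < 3:
        raise ValueError("need at least 3 pairs")
    d = xa - ya
    m = (xa + ya) / 2.0
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if np.ptp(m) > 0:
        slope = float(stats.linregress(m, d).slope)
    else:
        slope = 0.0
    return BlandAltmanResult(
        mean_difference=bias,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        sd_differences=sd,
        proportional_bias_slope=slope,
        n=len(xa),
    )


def _pb_point_estimates(xa: np.ndarray, ya: np.ndarray) -> tuple[np.ndarray, int]:
    """Sorted valid pairwise slopes and the offset K (# slopes < −1)."""
    n = len(xa)
    slopes = []
    for i in range(n - 1):
        dx = xa[i + 1 :] - xa[i]
        dy = ya[i + 1 :] - ya[i]
        mask = dx != 0
        s = dy[mask] / dx[mask]
        slopes.append(s[s != -1.0])  # slope −1 is undirected noise; excluded
    all_s = np.sort(np.concatenate(slopes))
    if all_s.size == 0:
        raise ValueError("all x values identical: Passing-Bablok undefined")
    k = int((all_s < -1.0).sum())
    return all_s, k


def _shifted_median(sorted_s: np.ndarray, k: int) -> float:
    n = len(sorted_s)
    if n % 2 == 1:
        return float(sorted_s[(n + 1) // 2 + k - 1])
    return float(0.5 * (sorted_s[n // 2 + k - 1] + sorted_s[n // 2 + k]))


def passing_bablok(x: Sequence[float], y: Sequence[float]) -> PassingBablokResult:
    """Passing–Bablok structural regression of y on x.

    The slope is the K-shifted median of all pairwise slopes
    ``(y_j − y_i)/(x_j − x_i)`` (slopes of exactly −1 excluded, K = number of
    slopes below −1, which makes the estimate invariant to axis exchange up
    to inversion); the intercept is ``median(y − slope·x)``.  The 95% CI uses
    the classical rank-based normal approximation; at least ~10 pairs are
    recommended for it to be meaningful.
    """
    xa, ya = np.asarray(x, float), np.asarray(y, float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be paired 1-d sequences")
    n = len(xa)
    if n < 3:
        raise ValueError("need at least 3 points")
    sorted_s, k = _pb_point_estimates(xa, ya)
    slope = _shifted_median(sorted_s, k)
    big_n = len(sorted_s)
    # rank-based normal-approximation CI (Kendall-type variance)
    w = 1.959963984540054 * math.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(round((big_n - w) / 2.0))
    m2 = big_n - m1 + 1
    lo_idx = max(m1 + k, 1)
    hi_idx = min(m2 + k, big_n)
    slope_lo = float(sorted_s[lo_idx - 1])
    slope_hi = float(sorted_s[hi_idx - 1])
    intercept = float(np.median(ya - slope * xa))
    intercept_ci = (
        float(np.median(ya - slope_hi * xa)),
        float(np.median(ya - slope_lo * xa)),
    )
    return PassingBablokResult(
        slope=slope,
        slope_ci_95=(slope_lo, slope_hi),
        intercept=intercept,
        intercept_ci_95=intercept_ci,
        n_pairs=n,
    )


def recovery_analysis(
    spike_conc: float,
    dilution_factors: Sequence[float],
    observed: Sequence[Sequence[float]],
) -> RecoveryResult:
    """Spike recovery across a serial-dilution series.

    ``observed[i]`` holds replicate measurements at dilution
    ``dilution_factors[i]``; the expected concentration at each level is
    ``spike_conc / dilution``.  Percent recovery is 100·mean(observed)/
    expected (SD taken across per-replicate recoveries) and linearity is the
    Pearson r of all observed values against their expected levels.
    """
    if spike_conc <= 0:
        raise ValueError("spike concentration must be > 0")
    dil = np.asarray(dilution_factors, float)
    if (dil <= 0).any():
        raise ValueError("dilution factors must be > 0")
    expected = spike_conc / dil
    obs = [np.asarray(o, float) for o in observed]
    if len(obs) != len(expected) or any(len(o) == 0 for o in obs):
        raise ValueError("one non-empty replicate group per dilution level required")
    recovery = np.array([100.0 * o.mean() / e for o, e in zip(obs, expected)])
    rec_sd = np.array(
        [
            (100.0 * o / e).std(ddof=1) if len(o) > 1 else 0.0
            for o, e in zip(obs, expected)
        ]
    )
    all_obs = np.concatenate(obs)
    all_exp = np.concatenate([np.full(len(o), e) for o, e in zip(obs, expected)])
    if np.ptp(all_exp) > 0 and np.ptp(all_obs) > 0:
        linearity_r = float(stats.pearsonr(all_obs, all_exp).statistic)
    else:
        linearity_r = float("nan")
    return RecoveryResult(
        expected=expected,
        observed_mean=np.array([o.mean() for o in obs]),
        percent_recovery=recovery,
        recovery_sd=rec_sd,
        linearity_r=linearity_r,
    )


def precision_anova(runs: Sequence[Sequence[float]]) -> PrecisionResult:
    """Within- and between-run CVs by one-way random-effects ANOVA.

    The within-run variance is the pooled mean square within; the
    between-run variance component is ``max(0, (MS_between − MS_within)/n₀)``
    where n₀ is the replicates per run (harmonic mean for unbalanced
    designs, with a logged note).  CVs are 100·sd/grand mean.
    """
    groups = [np.asarray(g, float) for g in runs]
    k = len(groups)
    if k < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 runs with >= 2 replicates each")
    sizes = np.array([len(g) for g in groups], float)
    if len(set(sizes)) > 1:
        logger.info("precision_anova: unbalanced runs; using harmonic-mean n")
        n0 = stats.hmean(sizes)
    else:
        n0 = sizes[0]
    all_vals = np.concatenate(groups)
    grand = float(all_vals.mean())
    if grand <= 0:
        raise ValueError("grand mean must be positive for CV computation")
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_within = int(sizes.sum()) - k
    ms_within = ss_within / df_within
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ms_between = ss_between / (k - 1)
    var_between = max(0.0, (ms_between - ms_within) / n0)
    return PrecisionResult(
        grand_mean=grand,
        within_run_cv=100.0 * math.sqrt(ms_within) / grand,
        between_run_cv=100.0 * math.sqrt(var_between) / grand,
        ms_within=float(ms_within),
        ms_between=float(ms_between),
    )


def freeze_thaw_change(
    per_count_measurements: dict[int, Sequence[float]],
) -> StabilityResult:
    """Percent change from index (count-0) aliquots per freeze-thaw count.

    ``per_count_measurements`` maps the number of freeze-thaw cycles to the
    replicate measurements of aliquots that underwent that many cycles; the
    count-0 group is the index and must be present with a positive mean.
    Change is ``100·(mean(count) − index_mean)/index_mean`` with the SD of
    the per-replicate changes.
    """
    if 0 not in per_count_measurements:
        raise ValueError("index group (freeze-thaw count 0) is required")
    index = np.asarray(per_count_measurements[0], float)
    index_mean = float(index.mean())
    if index_mean <= 0:
        raise ValueError("index mean must be positive")
    counts = np.array(sorted(per_count_measurements), int)
    means, sds = [], []
    for c in counts:
        vals = np.asarray(per_count_measurements[c], float)
        changes = 100.0 * (vals - index_mean) / index_mean
        means.append(float(np.mean(vals - index_mean) / index_mean * 100.0))
        sds.append(float(changes.std(ddof=1)) if len(changes) > 1 else 0.0)
    return StabilityResult(
        counts=counts,
        mean_percent_change=np.array(means),
        sd_percent_change=np.array(sds),
        index_mean=index_mean,
    )


def cross_reactivity(
    spiked: Sequence[float],
    unspiked: Sequence[float],
    spike_conc: float,
) -> CrossReactivityResult:
    """Percent cross-reactivity from spiked vs unspiked matrix samples.

    ``100·(mean(spiked) − mean(unspiked))/spike_conc``: the fraction of the
    spiked cross-reactant (at ``spike_conc``, same units as the
    measurements) that the assay reads as its target analyte.
    """
    if spike_conc <= 0:
        raise ValueError("spike concentration must be > 0")
    sp = np.asarray(spiked, float)
    un = np.asarray(unspiked, float)
    if len(sp) == 0 or len(un) == 0:
        raise ValueError("need at least one measurement per group")
    return CrossReactivityResult(
        percent_cross_reactivity=100.0 * (sp.mean() - un.mean()) / spike_conc,
        spiked_mean=float(sp.mean()),
        unspiked_mean=float(un.mean()),
        spike_concentration=float(spike_conc),
    )
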