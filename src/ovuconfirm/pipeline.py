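"""Cohort-level analysis drivers: simulate → classify → ROC → method comparison.

Two study designs are analysed:

* **Daily (confirmatory) cohort** — ovulation day known.  Per cycle and
  platform the all-pairs median luteal percent change is computed; sample-
  and pair-level scores feed ROC curves.  For the single-sample ROC, luteal
  samples are positives and follicular samples negatives.  For the
  percent-rise ROC, follicular→luteal pairwise ratios are positives and
  within-follicular (earlier→later) ratios — pairs where no rise should be
  seen — are negatives.
* **Weekly (exploratory) cohort** — ovulation unknown; cycles are called
  (an)ovulatory by the PDG referent, and P4 calls are cross-tabulated
  against PDG per sample (single-sample threshold) and per ordered pair
  (percent rise), within ovulatory and anovulatory blocks separately.
  Peak values of sliding 4-sample windows feed a cycle-labelled ROC.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import (
    ClassifierConfig,
    ConfusionTable,
    build_confusion,
    call_cycle_by_pdg_referent,
    luteal_percent_change,
    weekly_pairwise_changes,
    window_peaks,
)
from .core import CycleRecord, Phase, assign_phase
from .rocstats import (
    AucComparison,
    DiagnosticSummary,
    RocCurve,
    delong_compare,
    diagnostics_from_table,
    roc_curve,
)

__all__ = [
    "DailyCohortResult",
    "WeeklyCohortResult",
    "phase_values",
    "daily_luteal_change_table",
    "daily_single_sample_scores",
    "daily_percent_rise_scores",
    "analyse_daily_cohort",
    "analyse_weekly_cohort",
]


def phase_values(cycle: CycleRecord, platform: str) -> tuple[list[float], list[float]]:
    """Corrected (follicular, luteal) values of a daily cycle for one platform."""
    foll, lut = [], []
    for s in cycle.samples:
        if (
            s.day_rel_ovulation is None
            or platform not in s.concentrations
            or not s.usable_for_correction
        ):
            continue
        phase = assign_phase(s.day_rel_ovulation)
        if phase is Phase.FOLLICULAR:
            foll.append(s.corrected(platform).value)
        elif phase is Phase.LUTEAL:
            lut.append(s.corrected(platform).value)
    return foll, lut


def daily_luteal_change_table(
    cycles: Sequence[CycleRecord], platforms: Sequence[str]
) -> pd.DataFrame:
    """Per-cycle median luteal percent change for each platform."""
    rows = []
    for cyc in cycles:
        if cyc.design != "daily":
            continue
        row: dict = {"cycle_id": cyc.cycle_id, "true_ovulatory": cyc.true_ovulatory}
        for p in platforms:
            res = luteal_percent_change(cyc, p)
            row[p] = res.median_percent_change
            row[f"{p}_n_pairs"] = res.n_pairs
        rows.append(row)
    return pd.DataFrame(rows)


def daily_single_sample_scores(
    cycles: Sequence[CycleRecord], platform: str
) -> tuple[np.ndarray, np.ndarray]:
    """Scores/labels for the single-sample ROC (luteal = positive)."""
    scores, labels = [], []
    for cyc in cycles:
        if cyc.design != "daily":
            continue
        foll, lut = phase_values(cyc, platform)
        scores.extend(foll)
        labels.extend([False] * len(foll))
        scores.extend(lut)
        labels.extend([True] * len(lut))
    return np.asarray(scores), np.asarray(labels, bool)


def daily_percent_rise_scores(
    cycles: Sequence[CycleRecord], platform: str
) -> tuple[np.ndarray, np.ndarray]:
    """Scores/labels for the percent-rise ROC.

    Positives: all follicular→luteal pairwise ratios (percent).  Negatives:
    earlier→later ratios within the follicular window, where no luteal rise
    exists by construction.
    """
    scores, labels = [], []
    for cyc in cycles:
        if cyc.design != "daily":
            continue
        foll, lut = phase_values(cyc, platform)
        for f in foll:
            if f <= 0:
                continue
            for l in lut:
                scores.append(100.0 * l / f)
                labels.append(True)
        for f1, f2 in itertools.combinations(foll, 2):  # day order preserved
            if f1 > 0:
                scores.append(100.0 * f2 / f1)
                labels.append(False)
    return np.asarray(scores), np.asarray(labels, bool)


@dataclass
class DailyCohortResult:
    luteal_change: pd.DataFrame
    median_luteal_change: dict[str, float]
    roc_single: dict[str, RocCurve]
    roc_rise: dict[str, RocCurve]
    auc_comparisons: dict[tuple[str, str, str], AucComparison] = field(
        default_factory=dict
    )


def analyse_daily_cohort(
    cycles: Sequence[CycleRecord],
    platforms: Sequence[str] = ("pdg", "p4_platform_a", "p4_platform_b"),
    compare: Sequence[tuple[str, str]] = (("pdg", "p4_platform_a"),),
) -> DailyCohortResult:
    """Full confirmatory-cohort analysis across platforms.

    Produces the per-cycle luteal-change table with its cohort medians,
    single-sample and percent-rise ROC curves per platform, and paired
    DeLong comparisons for the requested platform pairs in both ROC modes.
    """
    daily = [c for c in cycles if c.design == "daily"]
    table = daily_luteal_change_table(daily, platforms)
    medians = {
        p: float(table[p].dropna().median()) if p in table and table[p].notna().any() else float("nan")
        for p in platforms
    }
    roc_single, roc_rise = {}, {}
    for p in platforms:
        s, y = daily_single_sample_scores(daily, p)
        roc_single[p] = roc_curve(s, y) if len(s) else None
        s, y = daily_percent_rise_scores(daily, p)
        roc_rise[p] = roc_curve(s, y) if len(s) else None
    comparisons: dict[tuple[str, str, str], AucComparison] = {}
    for pa, pb in compare:
        sa, ya = daily_single_sample_scores(daily, pa)
        sb, yb = daily_single_sample_scores(daily, pb)
        if len(sa) == len(sb) and np.array_equal(ya, yb):
            comparisons[("single", pa, pb)] = delong_compare(sa, sb, ya)
        ra, la = daily_percent_rise_scores(daily, pa)
        rb, lb = daily_percent_rise_scores(daily, pb)
        if len(ra) == len(rb) and np.array_equal(la, lb):
            comparisons[("rise", pa, pb)] = delong_compare(ra, rb, la)
    return DailyCohortResult(
        luteal_change=table,
        median_luteal_change=medians,
        roc_single=roc_single,
        roc_rise=roc_rise,
        auc_comparisons=comparisons,
    )


@dataclass
class WeeklyCohortResult:
    cycle_calls: pd.DataFrame  # cycle_id, referent_call, p4_single_call, ...
    confusion_single: dict[str, ConfusionTable]  # block → table (per sample)
    confusion_rise: dict[str, ConfusionTable]  # block → table (per ordered pair)
    diagnostics_single: dict[str, DiagnosticSummary]
    diagnostics_rise: dict[str, DiagnosticSummary]
    peak_roc: Optional[RocCurve]
    n_uncallable: int = 0


def _weekly_series(cycle: CycleRecord, platform: str) -> list[Optional[float]]:
    by_week: dict[int, float] = {}
    for s in cycle.samples:
        if (
            s.week_index is not None
            and platform in s.concentrations
            and s.usable_for_correction
        ):
            by_week[s.week_index] = s.corrected(platform).value
    return [by_week.get(w) for w in range(1, 9)]


def analyse_weekly_cohort(
    cycles: Sequence[CycleRecord],
    config: Optional[ClassifierConfig] = None,
    p4_platform: str = "p4_platform_a",
    window: int = 4,
) -> WeeklyCohortResult:
    """Exploratory-cohort analysis with PDG as the referent.

    The P4 single-sample threshold used weekly is the config's dedicated
    weekly cutoff (default 1.67 µmol/mol); the referent PDG threshold and
    the rise thresholds are shared with the daily design.
    """
    config = config or ClassifierConfig()
    weekly = [c for c in cycles if c.design == "weekly"]
    rows = []
    single_calls: dict[str, tuple[list, list]] = {"ovulatory": ([], []), "anovulatory": ([], [])}
    rise_calls: dict[str, tuple[list, list]] = {"ovulatory": ([], []), "anovulatory": ([], [])}
    peak_scores, peak_labels = [], []
    n_uncallable = 0
    pdg_thr = config.threshold_for("pdg")
    p4_thr = config.weekly_p4_threshold
    pdg_rise_thr = config.rise_for("pdg")
    p4_rise_thr = config.rise_for("p4")

    for cyc in weekly:
        pdg = _weekly_series(cyc, "pdg")
        p4 = _weekly_series(cyc, p4_platform)
        try:
            referent, rise_week = call_cycle_by_pdg_referent(
                [v for v in pdg], config
            )
        except ValueError:
            n_uncallable += 1
            continue
        block = referent  # "ovulatory" | "anovulatory"
        # per-sample single-threshold calls on weeks where both assays read
        for pv, qv in zip(p4, pdg):
            if pv is None or qv is None:
                continue
            single_calls[block][0].append(pv > p4_thr)
            single_calls[block][1].append(qv > pdg_thr)
        # per-ordered-pair percent-rise calls
        usable = [(pv, qv) for pv, qv in zip(p4, pdg) if pv is not None and qv is not None]
        p4_changes = weekly_pairwise_changes([pv for pv, _ in usable])
        pdg_changes = weekly_pairwise_changes([qv for _, qv in usable])
        for pc, qc in zip(p4_changes, pdg_changes):
            rise_calls[block][0].append(pc > p4_rise_thr)
            rise_calls[block][1].append(qc > pdg_rise_thr)
        # sliding-window peak scores, cycle-level referent label
        p4_usable = [pv for pv in p4 if pv is not None]
        if len(p4_usable) >= window:
            for peak in window_peaks(p4_usable, window=window):
                peak_scores.append(peak)
                peak_labels.append(referent == "ovulatory")
        rows.append(
            {
                "cycle_id": cyc.cycle_id,
                "referent_call": referent,
                "referent_rise_week": rise_week,
                "true_ovulatory": cyc.true_ovulatory,
                "p4_single_call": any(
                    pv is not None and pv > p4_thr for pv in p4
                ),
                "p4_max_corrected": max(
                    (pv for pv in p4 if pv is not None), default=None
                ),
            }
        )

    confusion_single = {
        blk: build_confusion(t, r) for blk, (t, r) in single_calls.items() if t
    }
    confusion_rise = {
        blk: build_confusion(t, r) for blk, (t, r) in rise_calls.items() if t
    }
    diag = lambda tables: {
        blk: diagnostics_from_table(t.a, t.b, t.c, t.d) for blk, t in tables.items()
    }
    labels_arr = np.asarray(peak_labels, bool)
    peak_roc = (
        roc_curve(np.asarray(peak_scores), labels_arr)
        if len(peak_scores) and labels_arr.any() and not labels_arr.all()
        else None
    )
    return WeeklyCohortResult(
        cycle_calls=pd.DataFrame(rows),
        confusion_single=confusion_single,
        confusion_rise=confusion_rise,
        diagnostics_single=diag(confusion_single),
        diagnostics_rise=diag(confusion_rise),
        peak_roc=peak_roc,
        n_uncallable=n_uncallable,
    )
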