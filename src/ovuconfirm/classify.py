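"""Ovulation-confirmation procedures for daily and weekly sampling designs.

Two classifier families are implemented:

* a *single-sample threshold*: ovulation is confirmed when a
  creatinine-corrected value strictly exceeds an analyte-specific cutoff;
* a *percent rise* between two samples: ovulation is confirmed when
  ``100·later/earlier`` strictly exceeds a rise threshold.

"Percent change" throughout is the ratio expressed in percent
(``100·later/earlier``), not the percent increase: a doubling is 200%, an
unchanged pair is 100%, and rise thresholds ≥ 100% can never fire on a flat
series.  The per-cycle luteal summary statistic is the median of
``100·l/f`` over *all* (follicular, luteal) sample pairs, which is robust to
a single aberrant collection day.

In the weekly design, where ovulation timing is unknown, every ordered pair
among the 8 weekly samples is compared (8×7 = 56 combinations per woman),
and cycle-level referent calls are made from PDG: a cycle is deemed
ovulatory iff any weekly PDG value exceeds the PDG threshold.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from statistics import median
from typing import Optional, Sequence

from pydantic import BaseModel, Field

from .core import CorrectedValue, CycleRecord, Phase, assign_phase

logger = logging.getLogger("ovuconfirm")

__all__ = [
    "ClassifierConfig",
    "LutealChangeResult",
    "ConfusionTable",
    "luteal_percent_change",
    "classify_single_threshold",
    "classify_percent_rise",
    "weekly_pairwise_changes",
    "call_cycle_by_pdg_referent",
    "window_peaks",
    "build_confusion",
]


class ClassifierConfig(BaseModel):
    """Operating points for the two classifier families.

    ``threshold_value`` maps analyte → corrected-concentration cutoff in the
    canonical corrected unit of the analyte (µmol/mol for P4, mmol/mol for
    PDG); ``rise_threshold_percent`` maps analyte → ratio threshold in
    percent.  The shipped defaults are conventional daily-design operating
    points (P4 1.14 µmol/mol, PDG 0.208 mmol/mol; rises 165% / 195%) plus a
    weekly-design P4 cutoff of 1.67 µmol/mol; all are plain configuration —
    derive study-specific points with :func:`ovuconfirm.rocstats.youden_optimal`.
    """

    threshold_value: dict[str, float] = Field(
        default_factory=lambda: {"p4": 1.14, "pdg": 0.208}
    )
    rise_threshold_percent: dict[str, float] = Field(
        default_factory=lambda: {"p4": 165.0, "pdg": 195.0}
    )
    weekly_p4_threshold: float = 1.67

    def threshold_for(self, analyte: str) -> float:
        try:
            return self.threshold_value[analyte]
        except KeyError:
            raise KeyError(f"no threshold configured for analyte {analyte!r}") from None

    def rise_for(self, analyte: str) -> float:
        try:
            return self.rise_threshold_percent[analyte]
        except KeyError:
            raise KeyError(f"no rise threshold configured for analyte {analyte!r}") from None


@dataclass
class LutealChangeResult:
    """All-pairs follicular→luteal percent changes for one cycle × platform."""

    cycle_id: str
    platform: str
    pairwise_percent_changes: list[float] = field(default_factory=list)
    median_percent_change: Optional[float] = None
    n_pairs: int = 0
    defined: bool = True

    def __post_init__(self) -> None:
        self.n_pairs = len(self.pairwise_percent_changes)
        if self.n_pairs == 0:
            self.defined = False
            self.median_percent_change = None
        elif self.median_percent_change is None:
            self.median_percent_change = median(self.pairwise_percent_changes)


@dataclass(frozen=True)
class ConfusionTable:
    """2×2 counts: index-test call (rows) against referent call (columns).

    a = test+/referent+, b = test+/referent−, c = test−/referent+,
    d = test−/referent−.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def _corrected_series(cycle: CycleRecord, platform: str) -> list[tuple]:
    """Usable (sample, CorrectedValue) pairs for one platform; flags the rest."""
    out = []
    n_flagged = 0
    for s in cycle.samples:
        if platform not in s.concentrations or not s.usable_for_correction:
            n_flagged += 1
            continue
        out.append((s, s.corrected(platform)))
    if n_flagged:
        logger.info(
            "cycle %s platform %s: %d samples unusable for corrected analysis",
            cycle.cycle_id, platform, n_flagged,
        )
    return out


def luteal_percent_change(cycle: CycleRecord, platform: str) -> LutealChangeResult:
    """Median ratio (in percent) over all follicular × luteal sample pairs.

    Requires a daily-design cycle with day-of-ovulation-relative timing; the
    follicular window is day −10..−3, the luteal window +3..+10.  An empty
    window yields a flagged, undefined result rather than an exception.
    """
    follicular, luteal = [], []
    for s, cv in _corrected_series(cycle, platform):
        if s.day_rel_ovulation is None:
            continue
        phase = assign_phase(s.day_rel_ovulation)
        if phase is Phase.FOLLICULAR:
            follicular.append(cv.value)
        elif phase is Phase.LUTEAL:
            luteal.append(cv.value)
    if not follicular or not luteal:
        return LutealChangeResult(cycle.cycle_id, platform, [], defined=False)
    changes = [100.0 * l / f for f in follicular for l in luteal if f > 0]
    return LutealChangeResult(cycle.cycle_id, platform, changes)


def classify_single_threshold(
    corrected: CorrectedValue, config: ClassifierConfig, analyte: str
) -> bool:
    """True iff the corrected value strictly exceeds the analyte's cutoff."""
    return corrected.value > config.threshold_for(analyte)


def classify_percent_rise(
    earlier: CorrectedValue, later: CorrectedValue, config: ClassifierConfig,
    analyte: str,
) -> bool:
    """True iff 100·later/earlier strictly exceeds the analyte's rise threshold."""
    if earlier.value <= 0:
        raise ValueError("percent rise undefined for non-positive earlier value")
    return 100.0 * later.value / earlier.value > config.rise_for(analyte)


def weekly_pairwise_changes(series: Sequence[float]) -> list[float]:
    """Percent changes for all ordered pairs of a weekly series.

    For the full 8-sample series this yields 8×7 = 56 combinations; with n
    usable samples, n·(n−1).  Pairs with a zero denominator are flagged and
    excluded, shrinking the count.
    """
    values = list(series)
    changes = []
    n_flagged = 0
    for i, j in itertools.permutations(range(len(values)), 2):
        if values[j] <= 0:
            n_flagged += 1
            continue
        changes.append(100.0 * values[i] / values[j])
    if n_flagged:
        logger.info("weekly series: %d pairs flagged for zero denominator", n_flagged)
    return changes


def call_cycle_by_pdg_referent(
    pdg_series: Sequence[float], config: ClassifierConfig
) -> tuple[str, Optional[int]]:
    """Referent cycle call from weekly PDG: ('ovulatory'|'anovulatory', rise week).

    A cycle is ovulatory iff any weekly corrected PDG strictly exceeds the
    PDG threshold; the week of the first exceedance is reported (used for
    aligning weekly plots).  An all-missing series raises — the cycle is
    uncallable, not anovulatory.
    """
    values = [v for v in pdg_series if v is not None]
    if not values:
        raise ValueError("no PDG values: cycle uncallable")
    thr = config.threshold_for("pdg")
    for week, v in enumerate(pdg_series, start=1):
        if v is not None and v > thr:
            return "ovulatory", week
    return "anovulatory", None


def window_peaks(series: Sequence[float], window: int = 4) -> list[float]:
    """Peak value of each sliding block of ``window`` consecutive samples.

    8 weekly samples with a 4-sample window give 5 peaks (weeks 1–4, 2–5,
    …, 5–8).  Set ``window`` equal to the series length for a single
    whole-series peak; disjoint blocking can be had by slicing the result.
    """
    values = list(series)
    if len(values) < window:
        raise ValueError(f"series of length {len(values)} shorter than window {window}")
    return [max(values[i : i + window]) for i in range(len(values) - window + 1)]


def build_confusion(
    test_calls: Sequence[bool], referent_calls: Sequence[bool]
) -> ConfusionTable:
    """Cross-tabulate paired boolean calls (index test rows, referent columns)."""
    if len(test_calls) != len(referent_calls):
        raise ValueError("call sequences must be paired (equal length)")
    a = b = c = d = 0
    for t, r in zip(test_calls, referent_calls):
        if t and r:
            a += 1
        elif t and not r:
            b += 1
        elif not t and r:
            c += 1
        else:
            d += 1
    return ConfusionTable(a, b, c, d)
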