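"""Domain types, unit conventions, creatinine correction and cycle-phase assignment.

Canonical internal units
------------------------
* progesterone (P4) concentration: nmol/L
* pregnanediol-3-glucuronide (PDG) concentration: µmol/L
* urinary creatinine: mmol/L
* creatinine-corrected ratios: µmol analyte / mol creatinine for P4
  (nmol/L ÷ mmol/L), mmol/mol for PDG (µmol/L ÷ mmol/L)

Published work in this area mixes "nmol/mol", "µmol/mmol" and "mmol/mol"
labels for the same ratios; keeping one canonical unit per analyte and
tagging every corrected value avoids silent 1000× errors.  Rescaling to
other unit labels happens only at report time.

Timing convention: day 0 is the day of ovulation (LH-surge anchored);
cycle days are 1-based.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

logger = logging.getLogger("ovuconfirm")

#: days relative to ovulation counted as follicular, inclusive
FOLLICULAR_WINDOW = (-10, -3)
#: days relative to ovulation counted as luteal, inclusive
LUTEAL_WINDOW = (3, 10)

#: corrected-ratio unit tag per analyte under the canonical convention
CORRECTED_UNIT = {"p4": "umol/mol", "pdg": "mmol/mol"}


class UnusableSampleError(ValueError):
    """A sample cannot enter a corrected analysis (e.g. non-positive creatinine).

    Batch code catches this to flag-and-count rather than silently drop.
    """


class Phase(str, enum.Enum):
    """Cycle phase of a sample relative to the day of ovulation."""

    FOLLICULAR = "follicular"
    LUTEAL = "luteal"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class CorrectedValue:
    """A creatinine-corrected analyte value with explicit unit bookkeeping."""

    platform: str
    value: float
    unit: str

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"corrected value must be >= 0, got {self.value}")

    def as_mmol_per_mol(self) -> float:
        """Return the value on the mmol/mol scale (factor 1000 from µmol/mol)."""
        if self.unit == "mmol/mol":
            return self.value
        if self.unit == "umol/mol":
            return self.value / 1000.0
        raise ValueError(f"unknown unit tag {self.unit!r}")


@dataclass
class UrineSample:
    """One urine collection event.

    ``concentrations`` maps a platform identifier (e.g. ``"p4_platform_a"``,
    ``"pdg"``) to a raw concentration in the canonical unit for its analyte.
    Exactly one of ``day_rel_ovulation`` (daily design, 0 = ovulation day)
    and ``week_index`` (weekly design, 1..8) must be present.
    """

    subject_id: str
    cycle_id: str
    design: str  # "daily" | "weekly"
    concentrations: dict[str, float] = field(default_factory=dict)
    creatinine: Optional[float] = None
    day_rel_ovulation: Optional[int] = None
    week_index: Optional[int] = None
    freeze_thaw_count: int = 0

    def __post_init__(self) -> None:
        if self.design not in ("daily", "weekly"):
            raise ValueError(f"design must be 'daily' or 'weekly', got {self.design!r}")
        has_day = self.day_rel_ovulation is not None
        has_week = self.week_index is not None
        if self.design == "daily" and (not has_day or has_week):
            raise ValueError("daily sample needs day_rel_ovulation and no week_index")
        if self.design == "weekly" and (not has_week or has_day):
            raise ValueError("weekly sample needs week_index and no day_rel_ovulation")
        if has_week and not 1 <= int(self.week_index) <= 8:
            raise ValueError(f"week_index must be in 1..8, got {self.week_index}")
        if self.freeze_thaw_count < 0:
            raise ValueError("freeze_thaw_count must be non-negative")
        for platform, conc in self.concentrations.items():
            if conc < 0:
                raise ValueError(f"negative concentration for {platform}: {conc}")

    @property
    def usable_for_correction(self) -> bool:
        return self.creatinine is not None and self.creatinine > 0

    def corrected(self, platform: str, analyte: str | None = None) -> CorrectedValue:
        """Creatinine-corrected value for one platform on this sample."""
        if analyte is None:
            analyte = "pdg" if platform.startswith("pdg") else "p4"
        return correct_for_creatinine(
            self.concentrations[platform], self.creatinine, analyte=analyte,
            platform=platform,
        )


@dataclass
class CycleRecord:
    """Ordered samples for one cycle, with simulation ground truth when known."""

    cycle_id: str
    samples: list[UrineSample]
    cycle_length: Optional[int] = None
    ovulation_day: Optional[int] = None
    true_ovulatory: Optional[bool] = None

    def __post_init__(self) -> None:
        keys = [
            s.day_rel_ovulation if s.design == "daily" else s.week_index
            for s in self.samples
        ]
        if any(b <= a for a, b in zip(keys, keys[1:])):
            raise ValueError(f"sample days must be strictly increasing in {self.cycle_id}")
        if self.ovulation_day is not None and self.cycle_length is not None:
            if not 1 <= self.ovulation_day <= self.cycle_length:
                raise ValueError(
                    f"ovulation_day {self.ovulation_day} outside cycle 1..{self.cycle_length}"
                )

    @property
    def design(self) -> str:
        return self.samples[0].design if self.samples else "daily"


def correct_for_creatinine(
    concentration: float,
    creatinine: Optional[float],
    analyte: str = "p4",
    platform: str = "",
) -> CorrectedValue:
    """Divide an analyte concentration by urinary creatinine.

    Normalizes for hydration status: nmol/L ÷ mmol/L = µmol/mol (P4),
    µmol/L ÷ mmol/L = mmol/mol (PDG).

    Raises
    ------
    UnusableSampleError
        If creatinine is missing or not strictly positive; callers flag the
        sample rather than silently dropping it.
    """
    if creatinine is None or creatinine <= 0:
        raise UnusableSampleError(
            f"creatinine must be > 0 for corrected analyses (got {creatinine!r})"
        )
    if concentration < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration}")
    return CorrectedValue(
        platform=platform or analyte,
        value=concentration / creatinine,
        unit=CORRECTED_UNIT[analyte],
    )


def assign_phase(day_rel_ovulation: int) -> Phase:
    """Classify a collection day relative to ovulation (day 0).

    Days −10..−3 are follicular, +3..+10 luteal; everything else (the
    periovulatory days −2..+2 included) is excluded from phase contrasts.
    """
    d = int(day_rel_ovulation)
    if FOLLICULAR_WINDOW[0] <= d <= FOLLICULAR_WINDOW[1]:
        return Phase.FOLLICULAR
    if LUTEAL_WINDOW[0] <= d <= LUTEAL_WINDOW[1]:
        return Phase.LUTEAL
    return Phase.EXCLUDED


# ---------------------------------------------------------------------------
# Sample CSV schema
# ---------------------------------------------------------------------------

SAMPLE_CSV_COLUMNS = [
    "subject_id",
    "cycle_id",
    "design",
    "day_rel_ovulation",
    "week_index",
    "pdg",
    "p4_platform_a",
    "p4_platform_b",
    "creatinine",
    "freeze_thaw_count",
]

PLATFORM_COLUMNS = ["pdg", "p4_platform_a", "p4_platform_b"]


def samples_to_frame(cycles: list[CycleRecord]) -> pd.DataFrame:
    """Flatten cycle records to the one-row-per-sample CSV schema."""
    rows = []
    for cyc in cycles:
        for s in cyc.samples:
            row = {
                "subject_id": s.subject_id,
                "cycle_id": s.cycle_id,
                "design": s.design,
                "day_rel_ovulation": s.day_rel_ovulation,
                "week_index": s.week_index,
                "creatinine": s.creatinine,
                "freeze_thaw_count": s.freeze_thaw_count,
            }
            for col in PLATFORM_COLUMNS:
                row[col] = s.concentrations.get(col)
            rows.append(row)
    return pd.DataFrame(rows, columns=SAMPLE_CSV_COLUMNS)


def frame_to_cycles(
    frame: pd.DataFrame,
    truth: Optional[pd.DataFrame] = None,
) -> list[CycleRecord]:
    """Assemble :class:`CycleRecord` objects from the sample CSV schema.

    ``truth`` optionally carries cycle-level ground truth
    (cycle_id, true_ovulatory, ovulation_day, cycle_length).
    """
    missing = [c for c in SAMPLE_CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    truth_map: dict[str, dict] = {}
    if truth is not None:
        truth_map = truth.set_index("cycle_id").to_dict("index")
    cycles: list[CycleRecord] = []
    n_unusable = 0
    for cycle_id, grp in frame.groupby("cycle_id", sort=False):
        samples = []
        for _, r in grp.iterrows():
            conc = {
                col: float(r[col])
                for col in PLATFORM_COLUMNS
                if pd.notna(r[col])
            }
            creat = float(r["creatinine"]) if pd.notna(r["creatinine"]) else None
            if creat is None:
                n_unusable += 1
            samples.append(
                UrineSample(
                    subject_id=str(r["subject_id"]),
                    cycle_id=str(cycle_id),
                    design=str(r["design"]),
                    day_rel_ovulation=(
                        int(r["day_rel_ovulation"])
                        if pd.notna(r["day_rel_ovulation"])
                        else None
                    ),
                    week_index=(
                        int(r["week_index"]) if pd.notna(r["week_index"]) else None
                    ),
                    concentrations=conc,
                    creatinine=creat,
                    freeze_thaw_count=(
                        int(r["freeze_thaw_count"])
                        if pd.notna(r["freeze_thaw_count"])
                        else 0
                    ),
                )
            )
        info = truth_map.get(str(cycle_id), {})
        tv = info.get("true_ovulatory")
        cycles.append(
            CycleRecord(
                cycle_id=str(cycle_id),
                samples=samples,
                cycle_length=(
                    int(info["cycle_length"]) if "cycle_length" in info else None
                ),
                ovulation_day=(
                    int(info["ovulation_day"])
                    if info.get("ovulation_day") is not None
                    and pd.notna(info.get("ovulation_day"))
                    else None
                ),
                true_ovulatory=bool(tv) if tv is not None and pd.notna(tv) else None,
            )
        )
    if n_unusable:
        logger.info("%d samples missing creatinine: flagged, excluded from corrected analyses", n_unusable)
    return cycles
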