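"""Synthetic urinary hormone-cycle generator with platform-specific assay error.

The generator emulates the two study designs the analysis pipeline expects:

* a *daily* (confirmatory) design — one early-morning sample per cycle day,
  with the day of ovulation known, as when ovulation is dated by transvaginal
  ultrasound and the LH surge;
* a *weekly* (exploratory) design — eight samples at 7-day spacing starting
  on a uniformly random day of the cycle, ovulation status unknown.

Ground truth is a per-day creatinine-corrected hormone profile: a flat
log-normal follicular baseline per analyte, and for ovulatory cycles a
piecewise-linear luteal rise (days +1..+4 relative to ovulation), a plateau
at ``baseline × fold_change`` (days +4..+9) and a linear fall back to
baseline by day +13.  Anovulatory cycles keep the flat baseline throughout.
Raw concentrations are obtained by multiplying the corrected profile by a
per-sample log-normal creatinine draw, so that creatinine correction in the
analysis exactly undoes hydration variation.

Measured values are produced by :func:`apply_assay`, which layers
proportional/matrix bias, constant bias, PDG cross-reactivity, combined
within/between-run analytical noise and freeze-thaw loss on the true
concentration — the error structure an immunoassay validation exercise
(recovery, precision, cross-reactivity, stability) is designed to detect.
"""

from __future__ import annotations

import math
import zlib
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .core import CycleRecord, UrineSample, samples_to_frame

__all__ = [
    "CycleParams",
    "PlatformErrorModel",
    "SimulatedCohort",
    "simulate_cycle",
    "apply_assay",
    "simulate_cohort",
    "default_platform_models",
    "dilution_series_models",
]


class CycleParams(BaseModel):
    """Parameters of the true (pre-assay) hormone cycle.

    Defaults reflect a healthy regularly-cycling population: cycle length
    median 28 days (range 25–38), ovulation day median 14 (range 12–20),
    luteal fold changes of ≈4.27 for PDG and ≈2.8 for true P4, and
    follicular baselines chosen so that an accurate P4 platform reads a
    follicular median near 0.66 µmol/mol.
    """

    cycle_length_median: int = 28
    cycle_length_range: tuple[int, int] = (25, 38)
    cycle_length_sigma: float = 0.08  # log-scale spread of the discretized draw
    ovulation_day_median: int = 14
    ovulation_day_range: tuple[int, int] = (12, 20)
    ovulation_day_sigma: float = 0.10
    # true creatinine-corrected follicular baselines (canonical units:
    # p4 µmol/mol, pdg mmol/mol)
    follicular_level: dict[str, float] = Field(
        default_factory=lambda: {"p4": 0.58, "pdg": 0.05}
    )
    follicular_gcv: float = 0.35  # between-cycle geometric CV of the baseline
    luteal_fold_change: dict[str, float] = Field(
        default_factory=lambda: {"p4": 2.8, "pdg": 4.27}
    )
    # luteal profile shape: linear rise to day `rise_end`, plateau to
    # `plateau_end`, linear fall to baseline by `fall_end` (days after ovulation)
    rise_end: int = 4
    plateau_end: int = 9
    fall_end: int = 13
    day_cv: float = 0.30  # within-cycle day-to-day multiplicative noise
    creatinine_median: float = 10.0  # mmol/L
    creatinine_cv: float = 0.30
    anovulatory_fraction: float = Field(default=0.0, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check(self) -> "CycleParams":
        lo, hi = self.cycle_length_range
        if not lo <= self.cycle_length_median <= hi or lo > hi:
            raise ValueError("degenerate cycle-length distribution")
        lo, hi = self.ovulation_day_range
        if not lo <= self.ovulation_day_median <= hi or lo > hi:
            raise ValueError("degenerate ovulation-day distribution")
        if any(f < 1 for f in self.luteal_fold_change.values()):
            raise ValueError("luteal fold changes must be >= 1 for the ovulatory template")
        if not 0 < self.rise_end <= self.plateau_end < self.fall_end:
            raise ValueError("luteal shape breakpoints must be ordered")
        return self


class PlatformErrorModel(BaseModel):
    """Maps a true analyte concentration to a measured value for one platform.

    ``analyte`` names what the platform reports ("p4" or "pdg");
    ``crossreactivity_pdg`` only applies to P4 platforms and is the fraction
    of the PDG concentration (expressed in nmol/L) read as P4.
    """

    analyte: str = "p4"
    proportional_bias: float = 0.0
    constant_bias: float = 0.0  # canonical concentration units of the analyte
    matrix_factor: float = Field(default=1.0, gt=0.0)
    crossreactivity_pdg: float = Field(default=0.0, ge=0.0, lt=1.0)
    cv_within_run: float = Field(default=0.0, ge=0.0)
    cv_between_run: float = Field(default=0.0, ge=0.0)
    freeze_thaw_loss: float = Field(default=0.0, ge=0.0, lt=1.0)

    @property
    def total_cv(self) -> float:
        return math.hypot(self.cv_within_run, self.cv_between_run)


def dilution_series_models(
    base: PlatformErrorModel,
    dilution_factors: Sequence[float],
    matrix_decay: float = 0.25,
) -> list[PlatformErrorModel]:
    """Per-dilution-level error models for a spike-recovery experiment.

    Matrix interference is diluted along with the sample, so the effective
    over-recovery shrinks with the dilution factor d:
    ``matrix_factor(d) = 1 + (matrix_factor − 1)·d^(−matrix_decay)``.
    A platform with no matrix effect (factor 1) is unaffected.  Constant
    bias, expressed on the measured sample, is left unchanged.
    """
    return [
        base.model_copy(
            update={
                "matrix_factor": 1.0 + (base.matrix_factor - 1.0) * float(d) ** (-matrix_decay)
            }
        )
        for d in dilution_factors
    ]


def default_platform_models() -> dict[str, PlatformErrorModel]:
    """Error models for the three platforms the pipeline contrasts.

    * ``pdg`` — a specific competitive ELISA: unbiased in urine, ~8% total CV.
    * ``p4_platform_a`` — an accurate automated P4 immunoassay: mild
      over-recovery (~113%), 0.59% PDG cross-reactivity, ~2.6% loss per
      freeze-thaw cycle, CVs under 4%.
    * ``p4_platform_b`` — a matrix-affected automated P4 immunoassay:
      strong over-recovery plus a constant positive bias that inflates
      follicular readings and compresses the apparent luteal rise.
    """
    return {
        "pdg": PlatformErrorModel(
            analyte="pdg", cv_within_run=0.06, cv_between_run=0.06,
        ),
        "p4_platform_a": PlatformErrorModel(
            analyte="p4",
            matrix_factor=1.13,
            crossreactivity_pdg=0.0059,
            cv_within_run=0.025,
            cv_between_run=0.038,
            freeze_thaw_loss=0.026,
        ),
        "p4_platform_b": PlatformErrorModel(
            analyte="p4",
            matrix_factor=1.20,
            constant_bias=8.0,
            crossreactivity_pdg=0.0054,
            cv_within_run=0.008,
            cv_between_run=0.014,
            freeze_thaw_loss=0.022,
        ),
    }


def _mean_one_lognormal(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with unit mean and the given coefficient of variation."""
    if cv <= 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size=size)


def _draw_discrete_lognormal(
    rng: np.random.Generator, median: int, sigma: float, bounds: tuple[int, int]
) -> int:
    val = int(round(math.exp(rng.normal(math.log(median), sigma))))
    return int(np.clip(val, bounds[0], bounds[1]))


def luteal_shape(day_rel: int, params: CycleParams) -> float:
    """Fraction of the full luteal elevation reached on a given day (0..1)."""
    d = day_rel
    if d <= 0 or d >= params.fall_end:
        return 0.0
    if d < params.rise_end:
        return d / params.rise_end
    if d <= params.plateau_end:
        return 1.0
    return (params.fall_end - d) / (params.fall_end - params.plateau_end)


def _cycle_rng(master_seed: int, cycle_id: str) -> np.random.Generator:
    # keyed on (seed, crc32(cycle_id)): stable under cohort reordering
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), zlib.crc32(cycle_id.encode())])
    )


def simulate_cycle(
    params: CycleParams,
    design: str = "daily",
    seed: int | np.random.Generator = 0,
    cycle_id: str = "cycle",
    subject_id: str = "subject",
    ovulatory: Optional[bool] = None,
) -> CycleRecord:
    """Simulate the *true* hormone series for one cycle.

    Samples carry true raw concentrations under platform keys ``"p4"`` and
    ``"pdg"`` (canonical units) plus a per-sample creatinine; measured
    platform values are added by :func:`simulate_cohort` /
    :func:`apply_assay`.

    For the weekly design the eight samples start on a uniformly random
    cycle day and the cycle profile repeats with the same length, so later
    weeks wrap into the following (identically parameterized) cycle.
    """
    if design not in ("daily", "weekly"):
        raise ValueError(f"unknown design {design!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    cycle_length = _draw_discrete_lognormal(
        rng, params.cycle_length_median, params.cycle_length_sigma,
        params.cycle_length_range,
    )
    ov_hi = min(params.ovulation_day_range[1], cycle_length - 10)
    ov_bounds = (min(params.ovulation_day_range[0], ov_hi), ov_hi)
    ovulation_day = _draw_discrete_lognormal(
        rng, min(params.ovulation_day_median, ov_hi), params.ovulation_day_sigma,
        ov_bounds,
    )
    if ovulatory is None:
        ovulatory = bool(rng.random() >= params.anovulatory_fraction)

    analytes = sorted(params.follicular_level)
    base = {
        a: params.follicular_level[a]
        * _mean_one_lognormal(rng, params.follicular_gcv)
        for a in analytes
    }
    fold = {
        a: (params.luteal_fold_change[a] if ovulatory else 1.0) for a in analytes
    }

    def true_corrected(day_in_cycle: int) -> dict[str, float]:
        d_rel = day_in_cycle - ovulation_day
        s = luteal_shape(d_rel, params)
        return {a: base[a] * (1.0 + (fold[a] - 1.0) * s) for a in analytes}

    samples: list[UrineSample] = []
    if design == "daily":
        schedule = [(day, day - ovulation_day, None) for day in range(1, cycle_length + 1)]
    else:
        start = int(rng.integers(1, cycle_length + 1))
        schedule = []
        for w in range(8):
            day_abs = start + 7 * w
            day_in_cycle = (day_abs - 1) % cycle_length + 1
            schedule.append((day_in_cycle, None, w + 1))

    for day_in_cycle, day_rel, week in schedule:
        corrected = true_corrected(day_in_cycle)
        noise = {a: _mean_one_lognormal(rng, params.day_cv) for a in analytes}
        creatinine = params.creatinine_median * _mean_one_lognormal(
            rng, params.creatinine_cv
        )
        conc = {a: corrected[a] * noise[a] * creatinine for a in analytes}
        samples.append(
            UrineSample(
                subject_id=subject_id,
                cycle_id=cycle_id,
                design=design,
                day_rel_ovulation=day_rel,
                week_index=week,
                concentrations=conc,
                creatinine=creatinine,
            )
        )
    return CycleRecord(
        cycle_id=cycle_id,
        samples=samples,
        cycle_length=cycle_length,
        ovulation_day=ovulation_day,
        true_ovulatory=ovulatory,
    )


def apply_assay(
    true_p4: float,
    true_pdg: float,
    model: PlatformErrorModel,
    freeze_thaw_count: int = 0,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Measured concentration for one sample on one platform.

    ``true_p4`` is in nmol/L, ``true_pdg`` in µmol/L.  The deterministic part
    is ``target·(1+proportional_bias)·matrix_factor + constant_bias +
    crossreactivity·PDG(nmol/L)`` (cross-reactivity for P4 platforms only);
    a mean-one log-normal factor carries the combined within/between-run CV,
    and each freeze-thaw cycle removes a fixed fraction.  Results clip at 0.
    """
    if true_p4 < 0 or true_pdg < 0 or freeze_thaw_count < 0:
        raise ValueError("inputs must be non-negative")
    target = true_p4 if model.analyte == "p4" else true_pdg
    measured = target * (1.0 + model.proportional_bias) * model.matrix_factor
    measured += model.constant_bias
    if model.analyte == "p4":
        measured += model.crossreactivity_pdg * true_pdg * 1000.0  # µmol/L → nmol/L
    cv = model.total_cv
    if cv > 0:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        measured *= _mean_one_lognormal(rng, cv)
    measured *= (1.0 - model.freeze_thaw_loss) ** freeze_thaw_count
    return max(measured, 0.0)


class SimulatedCohort(BaseModel):
    """A reproducible bundle of simulated cycles plus its generating recipe."""

    model_config = {"arbitrary_types_allowed": True}

    cycles: list  # list[CycleRecord]
    seed: int
    params: CycleParams
    platform_models: dict[str, PlatformErrorModel]

    def to_sample_frame(self) -> pd.DataFrame:
        return samples_to_frame(self.cycles)

    def to_truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cycle_id": c.cycle_id,
                    "true_ovulatory": c.true_ovulatory,
                    "ovulation_day": c.ovulation_day,
                    "cycle_length": c.cycle_length,
                }
                for c in self.cycles
            ]
        )


# platform key → sample CSV column
_PLATFORM_COLUMN = {"pdg": "pdg", "p4_platform_a": "p4_platform_a", "p4_platform_b": "p4_platform_b"}


def simulate_cohort(
    n_daily_cycles: int,
    n_weekly_subjects: int,
    params: Optional[CycleParams] = None,
    platform_models: Optional[dict[str, PlatformErrorModel]] = None,
    anovulatory_fraction: Optional[float] = None,
    master_seed: int = 0,
    weekly_cycles_per_subject: int = 2,
    freeze_thaw_schedule: Optional[dict[str, int]] = None,
) -> SimulatedCohort:
    """Simulate a confirmatory (daily) and/or exploratory (weekly) cohort.

    Each cycle gets a child random generator derived deterministically from
    ``master_seed`` and its cycle id, so the output is byte-identical under
    regeneration and stable when cycles are added or reordered.  Daily cycles
    are ovulatory unless ``anovulatory_fraction`` says otherwise (it defaults
    to ``params.anovulatory_fraction`` for daily and is applied per cycle).

    ``freeze_thaw_schedule`` maps platform → number of freeze-thaw cycles the
    aliquot has seen when that platform measures it (assays run sequentially
    on stored aliquots); default is 0 for all platforms.
    """
    if n_daily_cycles < 0 or n_weekly_subjects < 0:
        raise ValueError("cohort counts must be >= 0")
    params = params or CycleParams()
    if platform_models is None:
        platform_models = default_platform_models()
    unknown = set(platform_models) - set(_PLATFORM_COLUMN)
    if unknown:
        raise ValueError(f"unknown platform identifiers: {sorted(unknown)}")
    if anovulatory_fraction is None:
        anovulatory_fraction = params.anovulatory_fraction
    freeze_thaw_schedule = freeze_thaw_schedule or {}

    cycles: list[CycleRecord] = []
    specs: list[tuple[str, str, str]] = []  # (cycle_id, subject_id, design)
    for i in range(n_daily_cycles):
        specs.append((f"daily-{i:03d}", f"dsub-{i % max(n_daily_cycles, 1):03d}", "daily"))
    for j in range(n_weekly_subjects):
        for k in range(weekly_cycles_per_subject):
            specs.append((f"weekly-{j:03d}-{k}", f"wsub-{j:03d}", "weekly"))

    for cycle_id, subject_id, design in specs:
        rng = _cycle_rng(master_seed, cycle_id)
        ovulatory = bool(rng.random() >= anovulatory_fraction)
        cyc = simulate_cycle(
            params, design=design, seed=rng, cycle_id=cycle_id,
            subject_id=subject_id, ovulatory=ovulatory,
        )
        for s in cyc.samples:
            true_p4_conc = s.concentrations.pop("p4")
            true_pdg_conc = s.concentrations.pop("pdg")
            for platform, model in platform_models.items():
                ftc = freeze_thaw_schedule.get(platform, 0)
                s.concentrations[_PLATFORM_COLUMN[platform]] = apply_assay(
                    true_p4_conc, true_pdg_conc, model,
                    freeze_thaw_count=ftc, seed=rng,
                )
            s.concentrations["p4_true"] = true_p4_conc
            s.concentrations["pdg_true"] = true_pdg_conc
            s.freeze_thaw_count = max(freeze_thaw_schedule.values(), default=0)
        cycles.append(cyc)

    return SimulatedCohort(
        cycles=cycles, seed=int(master_seed), params=params,
        platform_models=platform_models,
    )
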