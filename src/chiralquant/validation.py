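"""Bioanalytical validation statistics.

Implements the standard EMA-style figures of merit for a multi-residue
method: accuracy and intraday/interday precision of replicate injections,
relative retention time, matrix signal suppression from post-extraction
spikes, absolute and relative SPE recovery from pre-extraction spikes,
blank-subtracted method accuracy/precision in matrix, and whole-method
detection limits obtained from instrument limits, average relative
recovery and the SPE concentration factor:

    mLOD = iLOD * 100 / (Rec_average * CF)

Percent-scale conventions: accuracy of 100% is ideal; signal suppression
is positive when matrix reduces response and negative for enhancement;
relative recovery of 100% means complete extraction after internal-
standard correction.  Sample standard deviations use the n-1 denominator
throughout (triplicate bioanalytical convention).  Metrics whose
denominator is non-positive are undefined and returned as NaN rather than
sign-flipped percentages; precondition violations raise ``ValueError``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ReplicateSet",
    "AreaTriplet",
    "MethodLimits",
    "accuracy",
    "intraday_precision",
    "interday_repeatability",
    "relative_retention",
    "signal_suppression",
    "absolute_recovery",
    "relative_recovery",
    "average_recovery",
    "method_accuracy",
    "method_precision",
    "method_limits",
]


@dataclass(frozen=True)
class ReplicateSet:
    """Replicate concentration measurements at one nominal level."""

    nominal_x: float
    measurements: tuple[float, ...]
    day_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "measurements",
                           tuple(float(m) for m in self.measurements))
        if not self.measurements:
            raise ValueError("at least one measurement required")

    @property
    def mean(self) -> float:
        return float(np.mean(self.measurements))

    @property
    def sd(self) -> float:
        if len(self.measurements) < 2:
            raise ValueError("sample SD needs n >= 2")
        return float(np.std(self.measurements, ddof=1))


@dataclass(frozen=True)
class AreaTriplet:
    """Peak areas feeding signal suppression and absolute recovery:
    spiked matrix, matrix blank, and the matching mobile-phase QC."""

    area_spiked_matrix: float
    area_blank_matrix: float
    area_qc: float

    def __post_init__(self) -> None:
        if self.area_qc <= 0:
            raise ValueError("area_qc must be > 0")


@dataclass(frozen=True)
class MethodLimits:
    """Instrument and whole-method detection/quantification limits."""

    ilod: float
    iloq: float
    rec_average: float
    cf: float
    mlod: float
    mloq: float


def accuracy(rep: ReplicateSet) -> float:
    """Instrument accuracy (%): nominal / mean(measured) x 100."""
    if rep.nominal_x <= 0:
        raise ValueError("accuracy needs nominal_x > 0")
    if rep.mean <= 0:
        return math.nan
    return rep.nominal_x / rep.mean * 100.0


def intraday_precision(rep: ReplicateSet) -> float:
    """Intraday precision (%RSD) of replicate injections."""
    if len(rep.measurements) < 2:
        raise ValueError("precision needs n >= 2")
    if rep.mean <= 0:
        return math.nan
    return rep.sd / rep.mean * 100.0


def interday_repeatability(days: Sequence[ReplicateSet]) -> float:
    """Repeatability: arithmetic mean of each day's intraday %RSD."""
    if len(days) < 2:
        raise ValueError("interday repeatability needs >= 2 days")
    return float(np.mean([intraday_precision(d) for d in days]))


def relative_retention(t_analyte: float, t_istd: float) -> float:
    """Relative retention time t_rel = t_A / t_ISTD."""
    if t_istd <= 0:
        raise ValueError("internal-standard retention time must be > 0")
    return t_analyte / t_istd


def _blank_corrected_ratio_percent(areas: AreaTriplet) -> float:
    return ((areas.area_spiked_matrix - areas.area_blank_matrix)
            / areas.area_qc * 100.0)


def signal_suppression(areas: AreaTriplet) -> float:
    """Matrix signal suppression (%) from a post-extraction spike.

    SS = (1 - (spiked matrix - matrix blank) / QC) x 100.  Negative values
    indicate signal enhancement in matrix.  Computed as the exact
    complement of :func:`absolute_recovery`, with which it shares the
    blank-corrected area ratio, so the two always sum to 100.
    """
    return 100.0 - _blank_corrected_ratio_percent(areas)


def absolute_recovery(areas: AreaTriplet) -> float:
    """Absolute SPE recovery (%) from raw areas of a pre-extraction spike:
    (spiked matrix - matrix blank) / QC x 100."""
    return _blank_corrected_ratio_percent(areas)


def relative_recovery(conc_spiked_matrix: float,
                      conc_blank_matrix: float,
                      nominal_spike: float) -> float:
    """Relative recovery (%) from internal-standard-corrected concentrations:
    (measured spiked - measured blank) / nominal spike x 100.

    May be negative when the spiked measurement falls below the blank;
    callers should treat negative values as flagged.
    """
    if nominal_spike <= 0:
        raise ValueError("nominal_spike must be > 0")
    return (conc_spiked_matrix - conc_blank_matrix) / nominal_spike * 100.0


def average_recovery(per_level: Sequence[float]) -> tuple[float, float]:
    """Rec_average: unweighted mean of per-level relative recoveries, with
    the across-level SD of those level means."""
    if not per_level:
        raise ValueError("no recovery levels supplied")
    arr = np.asarray(per_level, dtype=float)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def method_accuracy(rep: ReplicateSet, blank_mean: float) -> float:
    """Method accuracy (%) in matrix with blank subtraction:
    nominal / mean(measured - blank) x 100; NaN when the blank-subtracted
    mean is non-positive."""
    if rep.nominal_x <= 0:
        raise ValueError("method accuracy needs nominal_x > 0")
    corrected_mean = rep.mean - blank_mean
    if corrected_mean <= 0:
        return math.nan
    return rep.nominal_x / corrected_mean * 100.0


def method_precision(rep: ReplicateSet, blank_mean: float) -> float:
    """Method precision (%RSD) of blank-subtracted matrix measurements.

    Subtracting a constant blank leaves the SD unchanged but rescales the
    mean, so this differs from the raw-value RSD whenever the blank is
    nonzero."""
    if len(rep.measurements) < 2:
        raise ValueError("precision needs n >= 2")
    corrected = np.asarray(rep.measurements) - blank_mean
    mean = float(corrected.mean())
    if mean <= 0:
        return math.nan
    return float(np.std(corrected, ddof=1)) / mean * 100.0


def method_limits(ilod: float, iloq: float, rec_average: float,
                  cf: float) -> MethodLimits:
    """Whole-method limits: mLOD = iLOD * 100 / (Rec_average * CF), and the
    same with iLOQ for mLOQ.

    ``rec_average`` is on the percent scale; ``cf`` is the SPE
    concentration factor (initial matrix volume / final vial volume,
    default workflow 50 mL -> 0.5 mL giving 100).  A non-positive average
    recovery leaves the limits undefined and the analyte qualitative-only.
    """
    if cf <= 0:
        raise ValueError("concentration factor must be > 0")
    if rec_average <= 0:
        raise ValueError("rec_average must be > 0; analyte is qualitative-only")
    return MethodLimits(
        ilod=ilod,
        iloq=iloq,
        rec_average=rec_average,
        cf=cf,
        mlod=ilod * 100.0 / (rec_average * cf),
        mloq=iloq * 100.0 / (rec_average * cf),
    )
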