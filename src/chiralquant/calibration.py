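"""Internal-standard calibration, quantification and instrument limits.

Each compound (achiral analyte or single enantiomer channel) is calibrated
by ordinary unweighted least squares of the response ratio
(analyte area / assigned internal-standard area) on nominal vial
concentration.  The calibration blank carries no response-ratio
information and is excluded from the fit, but its S/N participates in the
instrument limit screen: iLOD is the lowest calibrant level whose mean S/N
over replicate injections reaches 3, iLOQ the lowest reaching 10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "QuantifiedValue",
    "DetectionLimits",
    "fit_calibration",
    "quantify",
    "determine_ilod_iloq",
    "classify_linearity",
    "R2_FULL_THRESHOLD",
    "R2_SEMI_THRESHOLD",
    "ILOD_SNR",
    "ILOQ_SNR",
]

#: Linearity thresholds: R^2 strictly above 0.997 is fully quantitative,
#: 0.990..0.997 inclusive is semi-quantitative, below 0.990 fails.
R2_FULL_THRESHOLD = 0.997
R2_SEMI_THRESHOLD = 0.990

#: S/N thresholds for the instrument detection / quantification limits.
ILOD_SNR = 3.0
ILOQ_SNR = 10.0


@dataclass(frozen=True)
class CalibrationPoint:
    """One replicate injection of one calibrant level."""

    nominal_concentration: float
    response_ratio: float
    replicate_index: int = 1
    mean_snr: float = math.nan

    def __post_init__(self) -> None:
        if self.nominal_concentration < 0:
            raise ValueError("nominal_concentration must be >= 0")
        if self.response_ratio < 0:
            raise ValueError("response_ratio must be >= 0")


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear response model for one compound."""

    slope: float
    intercept: float
    r_squared: float
    linear_range: tuple[float, float]
    n_points: int

    def __post_init__(self) -> None:
        low, high = self.linear_range
        if not high > low:
            raise ValueError("linear_range high must exceed low")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass(frozen=True)
class QuantifiedValue:
    """Back-calculated concentration with censoring/range flags."""

    concentration: float
    censored_zero: bool = False
    out_of_range: bool = False


def fit_calibration(points: Sequence[CalibrationPoint],
                    weighting: str = "none") -> CalibrationCurve:
    """Least-squares line of response ratio on concentration.

    Replicate-level points are used as given (no level averaging).  Zero
    (blank) levels are excluded from the regression.  Requires at least
    five distinct nonzero levels.  ``weighting`` selects the fit:
    ``"none"`` (default) is ordinary unweighted least squares; ``"1/x"``
    and ``"1/x2"`` weight squared residuals by 1/concentration and
    1/concentration^2 respectively, the usual choices when a calibration
    spans several orders of magnitude and the low end must quantify
    accurately.  R^2 is always the squared Pearson correlation of observed
    and fitted ratios (identical to ``rvalue**2`` for the unweighted fit).
    """
    nonzero = [p for p in points if p.nominal_concentration > 0]
    x = np.array([p.nominal_concentration for p in nonzero])
    y = np.array([p.response_ratio for p in nonzero])
    if np.unique(x).size < 5:
        raise ValueError("calibration needs >= 5 distinct nonzero levels")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in calibration concentrations")
    if weighting == "none":
        fit = stats.linregress(x, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
        r_squared = float(fit.rvalue ** 2)
    elif weighting in ("1/x", "1/x2"):
        # np.polyfit squares w * residual, so pass the square root weight
        w = 1.0 / np.sqrt(x) if weighting == "1/x" else 1.0 / x
        slope, intercept = (float(c) for c in np.polyfit(x, y, 1, w=w))
        fitted = slope * x + intercept
        r_squared = float(np.corrcoef(y, fitted)[0, 1] ** 2)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return CalibrationCurve(
        slope=slope,
        intercept=intercept,
        r_squared=min(r_squared, 1.0),
        linear_range=(float(x.min()), float(x.max())),
        n_points=int(x.size),
    )


def quantify(curve: CalibrationCurve, response_ratio: float) -> QuantifiedValue:
    """Invert the calibration: concentration = (ratio - intercept) / slope.

    Negative back-calculated values are censored to 0 and flagged; values
    outside the fitted linear range are returned but flagged out-of-range.
    """
    if curve.slope <= 0:
        raise ValueError("calibration slope must be > 0 to quantify")
    conc = (response_ratio - curve.intercept) / curve.slope
    if conc < 0:
        return QuantifiedValue(0.0, censored_zero=True)
    low, high = curve.linear_range
    return QuantifiedValue(conc, out_of_range=not (low <= conc <= high))


@dataclass(frozen=True)
class DetectionLimits:
    """Instrument LOD/LOQ from the S/N rule; NaN when no level qualifies."""

    ilod: float
    iloq: float

    @property
    def ilod_defined(self) -> bool:
        return not math.isnan(self.ilod)

    @property
    def iloq_defined(self) -> bool:
        return not math.isnan(self.iloq)


def determine_ilod_iloq(mean_snr_by_level: Mapping[float, float]) -> DetectionLimits:
    """Lowest calibrant levels with mean S/N >= 3 (iLOD) and >= 10 (iLOQ).

    ``mean_snr_by_level`` maps nominal concentration to the mean S/N over
    replicate injections; levels are screened in ascending concentration
    order and either limit may be undefined (NaN) if no level qualifies.
    """
    if not mean_snr_by_level:
        raise ValueError("empty level set")
    ilod = iloq = math.nan
    for level in sorted(mean_snr_by_level):
        snr = mean_snr_by_level[level]
        if math.isnan(ilod) and snr >= ILOD_SNR:
            ilod = level
        if math.isnan(iloq) and snr >= ILOQ_SNR:
            iloq = level
    return DetectionLimits(ilod=ilod, iloq=iloq)


def classify_linearity(r_squared: float) -> str:
    """'full' (R^2 > 0.997), 'semi' (0.990 <= R^2 <= 0.997) or 'fail'.

    The boundary R^2 = 0.997 is classed semi, matching the strict
    inequality used for full quantitation.
    """
    if not 0.0 <= r_squared <= 1.0 + 1e-12:
        raise ValueError("r_squared must lie in [0, 1]")
    if r_squared > R2_FULL_THRESHOLD:
        return "full"
    if r_squared >= R2_SEMI_THRESHOLD:
        return "semi"
    return "fail"
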