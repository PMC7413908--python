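"""Enantiomer pairing, resolution and enantiomeric fraction.

E1 and E2 label enantiomers purely by elution order (first/second eluting
on the chiral column); they are positional labels and never imply absolute
R/S configuration.

The enantiomeric fraction EF = [E1] / ([E1] + [E2]) is 0.5 for a racemate.
It is computed from quantified concentrations when a calibration exists,
because the two enantiomers can differ in recovery and suppression in
matrix; for mobile-phase standards raw areas are equivalent.  Censoring
follows environmental reporting practice: an enantiomer below the
quantification limit contributes zero, so single-enantiomer detections
yield EF 1.0 (E2 censored) or 0.0 (E1 censored) with a censoring flag, and
a pair with both enantiomers censored has undefined EF.

Enantiomeric resolution Rs = (t2 - t1) / (0.5 (w2 + w1)) uses apex times
and base peak widths; it requires both peaks to be detected, though not
necessarily quantifiable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .peaks import Peak

__all__ = [
    "EnantiomerPair",
    "pair_enantiomers",
    "resolution",
    "enantiomeric_fraction",
    "ef_from_concentrations",
    "AmbiguousPeaksError",
]


class AmbiguousPeaksError(ValueError):
    """More than two candidate peaks on a chiral analyte's channel."""


@dataclass(frozen=True)
class EnantiomerPair:
    """Linked first-/second-eluting enantiomer measurements.

    ``e1`` and ``e2`` each hold either a :class:`~chiralquant.peaks.Peak`
    (for resolution) or a quantified concentration (for EF), or ``None``
    when that enantiomer was not observed.  Censoring flags mark members
    below the quantification limit.
    """

    analyte: str
    e1: Peak | float | None
    e2: Peak | float | None
    censored_e1: bool = False
    censored_e2: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.e1, Peak) and isinstance(self.e2, Peak):
            # coincident apexes (unresolved pair, Rs = 0) are permitted
            if self.e1.t_apex > self.e2.t_apex:
                raise ValueError("E1 must not elute after E2")
        for member in (self.e1, self.e2):
            if isinstance(member, (int, float)) and member < 0:
                raise ValueError("enantiomer concentrations must be >= 0")


def pair_enantiomers(peaks: Sequence[Peak], analyte: str = "") -> EnantiomerPair:
    """Order 0-2 detected peaks of one chiral channel into an E1/E2 pair.

    The earlier-eluting peak becomes E1.  A missing peak is marked
    censored; more than two candidates is an ambiguity error listing them.
    """
    ordered = sorted(peaks, key=lambda p: p.t_apex)
    if len(ordered) > 2:
        apexes = ", ".join(f"{p.t_apex:.3f}" for p in ordered)
        raise AmbiguousPeaksError(
            f"{analyte or 'chiral analyte'}: {len(ordered)} candidate peaks "
            f"at t = {apexes} min; expected at most two")
    if len(ordered) == 2:
        return EnantiomerPair(analyte, ordered[0], ordered[1])
    if len(ordered) == 1:
        return EnantiomerPair(analyte, ordered[0], None, censored_e2=True)
    return EnantiomerPair(analyte, None, None,
                          censored_e1=True, censored_e2=True)


def resolution(pair: EnantiomerPair) -> float:
    """Enantiomeric resolution Rs = (t2 - t1) / (0.5 (w2 + w1)).

    Requires both peaks present with positive base widths; NaN with the
    pair's censor state otherwise.
    """
    if not (isinstance(pair.e1, Peak) and isinstance(pair.e2, Peak)):
        return math.nan
    w1, w2 = pair.e1.width_base, pair.e2.width_base
    if w1 <= 0 or w2 <= 0:
        raise ValueError("base peak widths must be > 0")
    return (pair.e2.t_apex - pair.e1.t_apex) / (0.5 * (w2 + w1))


def _member_concentration(member, censored: bool) -> float:
    if censored or member is None:
        return 0.0
    if isinstance(member, Peak):
        raise TypeError("EF needs concentrations, not peaks; quantify first")
    return float(member)


def enantiomeric_fraction(pair: EnantiomerPair) -> float:
    """EF = [E1] / ([E1] + [E2]) with censored members contributing zero.

    Returns NaN when both enantiomers are censored or zero (reported as
    '-' downstream).
    """
    c1 = _member_concentration(pair.e1, pair.censored_e1)
    c2 = _member_concentration(pair.e2, pair.censored_e2)
    if c1 + c2 <= 0:
        return math.nan
    return c1 / (c1 + c2)


def ef_from_concentrations(e1: float, e2: float,
                           censored_e1: bool = False,
                           censored_e2: bool = False) -> float:
    """Convenience wrapper computing EF straight from two concentrations."""
    return enantiomeric_fraction(EnantiomerPair(
        "", e1, e2, censored_e1=censored_e1, censored_e2=censored_e2))
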