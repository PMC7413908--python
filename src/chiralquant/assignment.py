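"""Internal-standard assignment.

Every analyte is quantified against one internal standard.  The choice
follows a fixed priority: (1) the analyte's own deuterated analog when it
is in the internal-standard mix; otherwise (2) the internal standard whose
relative retention time t_rel = t_analyte / t_istd is closest to 1, with
candidates tied within a tolerance (default 0.01 on |t_rel - 1|) broken by
the smallest signal-suppression distance (mean |SS_analyte - SS_ISTD| over
the available matrices, e.g. river water and wastewater); any remaining
tie falls back to lexicographic internal-standard name so the mapping is
deterministic and independent of input ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import AnalyteSpec

__all__ = ["AssignmentCandidate", "assign_internal_standards"]

#: Candidates whose |t_rel - 1| lies within this of the best are treated
#: as retention-time ties and ranked by suppression similarity instead.
DEFAULT_T_REL_TOLERANCE = 0.01


@dataclass(frozen=True)
class AssignmentCandidate:
    """One (analyte, internal standard) pairing under evaluation."""

    analyte: str
    istd: str
    t_rel: float
    ss_distance: float
    is_deuterated_analog: bool

    def __post_init__(self) -> None:
        if self.t_rel <= 0:
            raise ValueError("t_rel must be > 0")
        if self.ss_distance < 0:
            raise ValueError("ss_distance must be >= 0")


def _ss_distance(analyte: str, istd: str,
                 suppression: Mapping[str, Mapping[str, float]]) -> float:
    dists = []
    for table in suppression.values():
        if analyte in table and istd in table:
            dists.append(abs(table[analyte] - table[istd]))
    return float(np.mean(dists)) if dists else 0.0


def assign_internal_standards(
        analytes: Sequence[AnalyteSpec],
        istds: Sequence[AnalyteSpec],
        suppression: Mapping[str, Mapping[str, float]] | None = None,
        t_rel_tolerance: float = DEFAULT_T_REL_TOLERANCE) -> pd.DataFrame:
    """Map every analyte to an internal standard.

    ``suppression`` maps matrix id -> compound name -> signal suppression
    (%); it is only consulted to break retention-time ties and may be
    omitted.  Returns a frame with columns (analyte, istd, t_rel,
    ss_distance, rule_used); the mapping is total and deterministic.
    """
    if not istds:
        raise ValueError("at least one internal standard required")
    suppression = suppression or {}
    by_parent = {s.deuterated_parent: s for s in istds if s.deuterated_parent}

    rows = []
    for analyte in analytes:
        candidates = [AssignmentCandidate(
            analyte=analyte.name,
            istd=s.name,
            t_rel=analyte.mean_retention / s.mean_retention,
            ss_distance=_ss_distance(analyte.name, s.name, suppression),
            is_deuterated_analog=(s.deuterated_parent == analyte.name),
        ) for s in istds]

        if analyte.name in by_parent:
            chosen = next(c for c in candidates if c.is_deuterated_analog)
            rule = "deuterated_analog"
        else:
            best = min(abs(c.t_rel - 1.0) for c in candidates)
            tied = [c for c in candidates
                    if abs(c.t_rel - 1.0) <= best + t_rel_tolerance]
            if len(tied) > 1:
                chosen = min(tied, key=lambda c: (c.ss_distance, c.istd))
                rule = ("suppression_similarity"
                        if len({c.ss_distance for c in tied}) > 1
                        else "lexicographic")
            else:
                chosen = tied[0]
                rule = "relative_retention"
        rows.append({
            "analyte": chosen.analyte,
            "istd": chosen.istd,
            "t_rel": chosen.t_rel,
            "ss_distance": chosen.ss_distance,
            "rule_used": rule,
        })
    return pd.DataFrame(rows, columns=["analyte", "istd", "t_rel",
                                       "ss_distance", "rule_used"])
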