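"""Quantitative-status classification and report assembly.

An analyte channel earns one of three statuses:

* ``fully_quantitative`` — calibration R^2 above 0.997, every instrument
  and method accuracy within 100 +/- 20%, every precision below 20% RSD,
  and average relative recovery either inside 80-120% or, when outside,
  reproducible (across-level SD < 20 percentage points) and not extreme.
* ``semi_quantitative`` — one or more tolerated relaxations apply
  (R^2 between 0.990 and 0.997, an accuracy band violation, a precision
  above 20% RSD, or an irreproducible out-of-band recovery).
* ``qualitative`` — a required metric is undefined, linearity fails, or
  average recovery is extreme (outside a wide hard band, default 40-160%)
  or undefined: the compound can be detected but not meaningfully
  quantified.

Missing metrics always demote, never crash.  The printed-report italics
convention for semi-quantitative compounds is replaced by an explicit
status column with machine-readable reason codes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClassificationRules",
    "QuantStatus",
    "classify_analyte",
    "build_validation_report",
    "build_environmental_report",
    "CENSORED_TOKEN",
    "UNDEFINED_TOKEN",
]

#: Rendering of measurements below the method quantification limit.
CENSORED_TOKEN = "<LOQ"
#: Rendering of undefined chiral quantities (e.g. EF with both enantiomers censored).
UNDEFINED_TOKEN = "-"


@dataclass(frozen=True)
class ClassificationRules:
    """Config-driven decision thresholds (percent scale throughout)."""

    accuracy_band: tuple[float, float] = (80.0, 120.0)
    precision_max: float = 20.0
    recovery_band: tuple[float, float] = (80.0, 120.0)
    recovery_sd_max: float = 20.0
    recovery_hard_band: tuple[float, float] = (40.0, 160.0)


DEFAULT_RULES = ClassificationRules()


@dataclass(frozen=True)
class QuantStatus:
    status: str
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.status not in ("fully_quantitative", "semi_quantitative",
                               "qualitative"):
            raise ValueError(f"unknown status {self.status!r}")
        if self.status != "fully_quantitative" and not self.reasons:
            raise ValueError("non-full status requires at least one reason")


def _in_band(value: float, band: tuple[float, float]) -> bool:
    return band[0] <= value <= band[1]


def _scan(values: Sequence[float], label: str, band: tuple[float, float] | None,
          maximum: float | None, soft: list[str], hard: list[str]) -> None:
    values = [v for v in np.atleast_1d(np.asarray(values, dtype=float))]
    if not values:
        hard.append(f"{label}_undefined")
        return
    for v in values:
        if math.isnan(v):
            hard.append(f"{label}_undefined")
            return
    if band is not None and any(not _in_band(v, band) for v in values):
        soft.append(f"{label}_out_of_band")
    if maximum is not None and any(v >= maximum for v in values):
        soft.append(f"{label}_above_limit")


def classify_analyte(linearity_class: str,
                     instrument_accuracies: Sequence[float],
                     instrument_precisions: Sequence[float],
                     rec_average: float,
                     rec_sd: float,
                     method_accuracies: Sequence[float] = (),
                     method_precisions: Sequence[float] = (),
                     rules: ClassificationRules = DEFAULT_RULES) -> QuantStatus:
    """Combine validation metrics into a quantitative status.

    ``instrument_accuracies``/``method_accuracies`` are per-level accuracy
    percentages; precisions are per-level %RSD values; ``rec_average`` and
    ``rec_sd`` summarise relative recovery over the spike levels.  The
    decision is monotone: moving any single metric toward its ideal never
    demotes the status.
    """
    soft: list[str] = []
    hard: list[str] = []

    if linearity_class == "semi":
        soft.append("linearity_semi")
    elif linearity_class == "fail":
        hard.append("linearity_fail")
    elif linearity_class != "full":
        raise ValueError(f"unknown linearity class {linearity_class!r}")

    _scan(instrument_accuracies, "instrument_accuracy",
          rules.accuracy_band, None, soft, hard)
    _scan(instrument_precisions, "instrument_precision",
          None, rules.precision_max, soft, hard)
    if len(method_accuracies):
        _scan(method_accuracies, "method_accuracy",
              rules.accuracy_band, None, soft, hard)
    if len(method_precisions):
        _scan(method_precisions, "method_precision",
              None, rules.precision_max, soft, hard)

    if math.isnan(rec_average):
        hard.append("recovery_undefined")
    elif not _in_band(rec_average, rules.recovery_hard_band):
        hard.append("recovery_poor")
    elif not _in_band(rec_average, rules.recovery_band):
        # out of the quantitative band: tolerated outright when the
        # across-level SD shows it is reproducible, otherwise a relaxation
        if math.isnan(rec_sd) or rec_sd >= rules.recovery_sd_max:
            soft.append("recovery_out_of_band")

    if hard:
        return QuantStatus("qualitative", tuple(hard + soft))
    if soft:
        return QuantStatus("semi_quantitative", tuple(soft))
    return QuantStatus("fully_quantitative")


def _chiral_sort_key(compound: str) -> tuple[str, str]:
    # alphabetical by parent analyte with E1 before E2
    for prefix in ("E1-", "E2-"):
        if compound.startswith(prefix):
            return compound[3:].lower(), prefix
    return compound.lower(), ""


def build_validation_report(per_compound: pd.DataFrame,
                            statuses: Mapping[str, QuantStatus]) -> dict:
    """Shape per-compound validation metrics into report tables.

    ``per_compound`` is the tidy summary produced by the pipeline (one row
    per compound channel).  Returns a dict with the recovery/suppression
    table, the method-limits/accuracy/precision table, the chiral EF/Rs
    table and a JSON-ready summary carrying statuses and reason codes.
    Rows are ordered alphabetically by analyte with E1 before E2.
    """
    frame = per_compound.copy()
    if frame.empty:
        frame = pd.DataFrame(columns=["compound"])
    frame["status"] = [statuses[c].status if c in statuses else "qualitative"
                       for c in frame.get("compound", [])]
    frame["reasons"] = [";".join(statuses[c].reasons) if c in statuses else ""
                        for c in frame.get("compound", [])]
    if "compound" in frame.columns and len(frame):
        frame = frame.iloc[
            sorted(range(len(frame)),
                   key=lambda i: _chiral_sort_key(frame["compound"].iloc[i]))
        ].reset_index(drop=True)

    def take(cols: list[str]) -> pd.DataFrame:
        present = [c for c in cols if c in frame.columns]
        return frame[present].copy()

    tables = {
        "recovery_suppression": take([
            "compound", "matrix_id", "rec_average", "rec_sd",
            "abs_recovery", "ss_mean", "ss_sd", "status"]),
        "method_performance": take([
            "compound", "matrix_id", "mlod", "mloq",
            "method_accuracy_mean", "method_accuracy_sd",
            "method_precision_mean", "method_precision_sd", "status"]),
        "instrument_performance": take([
            "compound", "r_squared", "linearity_class", "ilod", "iloq",
            "instrument_accuracy_mean", "instrument_precision_mean",
            "interday_repeatability", "status"]),
        "chiral": take([
            "compound", "matrix_id", "ef_mean", "ef_sd",
            "rs_mean", "rs_sd", "status"]),
    }
    if "ef_mean" in frame.columns:
        tables["chiral"] = tables["chiral"].dropna(subset=["ef_mean", "rs_mean"],
                                                   how="all").reset_index(drop=True)
    summary = {
        "n_compounds": int(len(frame)),
        "statuses": {c: {"status": statuses[c].status,
                         "reasons": list(statuses[c].reasons)}
                     for c in statuses},
        "counts": {s: sum(1 for q in statuses.values() if q.status == s)
                   for s in ("fully_quantitative", "semi_quantitative",
                             "qualitative")},
    }
    return {"tables": tables, "summary": summary}


def build_environmental_report(concentrations: pd.DataFrame,
                               mloq_by_compound: Mapping[str, float],
                               chiral_stats: pd.DataFrame | None = None) -> pd.DataFrame:
    """Environmental-sample report with <LOQ censoring.

    ``concentrations`` needs columns (compound, analyte, enantiomer_label,
    matrix_id, concentration) with recovery-corrected sample-level
    concentrations in ug/L, one row per replicate injection.  Per matrix,
    compounds are averaged over all replicate injections of all samples;
    means below the compound's mLOQ (ug/L) are rendered as the ``<LOQ``
    token; numeric means are reported in ng/L with %RSD.  A compound with
    no mLOQ (qualitative-only) is censored unconditionally.  Chiral
    analytes carry EF and Rs columns from ``chiral_stats`` (columns
    analyte, matrix_id, ef_mean, ef_sd, rs_mean, rs_sd), with censored EF
    flagged and undefined values rendered as '-'.
    """
    rows = []
    for (matrix_id, compound), group in concentrations.groupby(
            ["matrix_id", "compound"], sort=True):
        values = group["concentration"].to_numpy(float)
        mean = float(values.mean())
        mloq = mloq_by_compound.get(compound, math.nan)
        censored = math.isnan(mloq) or mean < mloq
        sd_percent = (float(np.std(values, ddof=1)) / mean * 100.0
                      if (not censored and mean > 0 and values.size > 1) else math.nan)
        rows.append({
            "analyte": group["analyte"].iloc[0],
            "compound": compound,
            "enantiomer_label": group["enantiomer_label"].iloc[0],
            "matrix_id": matrix_id,
            "mean_concentration_ng_l": CENSORED_TOKEN if censored
            else mean * 1000.0,
            "sd_percent": CENSORED_TOKEN if censored else sd_percent,
            "n": int(values.size),
            "qualitative_only": math.isnan(mloq),
        })
    out = pd.DataFrame(rows, columns=[
        "analyte", "compound", "enantiomer_label", "matrix_id",
        "mean_concentration_ng_l", "sd_percent", "n", "qualitative_only"])
    if len(out):
        out = out.iloc[sorted(
            range(len(out)),
            key=lambda i: (_chiral_sort_key(out["compound"].iloc[i]),
                           out["matrix_id"].iloc[i]))].reset_index(drop=True)
    if chiral_stats is not None and len(chiral_stats):
        merged = chiral_stats.copy()
        for col in ("ef_mean", "rs_mean"):
            if col in merged.columns:
                merged[col] = merged[col].map(
                    lambda v: UNDEFINED_TOKEN if (isinstance(v, float)
                                                  and math.isnan(v)) else v)
        out = out.merge(merged, on=["analyte", "matrix_id"], how="left")
    return out
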