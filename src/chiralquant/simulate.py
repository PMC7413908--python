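"""Synthetic MRM study generator.

Emulates the data structure of a chiral/achiral SFC-MS/MS validation
campaign: an internal-standard calibration series spanning five orders of
magnitude, replicate QC
injections on multiple days, post-extraction-spiked matrix sets for signal
suppression, and pre-extraction-spiked river-water/wastewater sets with
analyte-specific SPE recovery, matrix suppression/enhancement and blank
background levels.

The measurement model is deliberately explicit so every downstream
statistic has a known ground truth:

* extraction recovery acts on the *amount* of analyte reaching the final
  vial (pre-extraction spikes only);
* matrix signal suppression acts on the *instrument response* of whatever
  is in the vial (pre- or post-extraction);
* the SPE concentration factor CF (default 100: 50 mL of sample
  reconstituted to 0.5 mL) maps sample concentration to vial concentration.

Peak areas can be produced two ways with an identical output schema:
rendering full time-intensity traces with additive Gaussian baseline noise
(:func:`render_chromatogram` + the peaks module), or the fast path
(:func:`emit_peak_table`) that draws areas directly with multiplicative
log-normal noise of a chosen CV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .peaks import PEAK_TABLE_COLUMNS, Trace

__all__ = [
    "AnalyteSpec",
    "MatrixSpec",
    "StudyDesign",
    "Sample",
    "DEFAULT_CALIBRATION_LEVELS",
    "DEFAULT_SPIKE_LEVELS",
    "CALIBRANT_ISTD_CONCENTRATION",
    "MATRIX_ISTD_CONCENTRATION",
    "GAUSSIAN_BASE_WIDTH_SIGMA",
    "generate_calibration_series",
    "generate_instrument_qc_set",
    "generate_spiked_matrix_set",
    "generate_signal_suppression_set",
    "generate_mobile_phase_qc_set",
    "render_chromatogram",
    "emit_peak_table",
    "ground_truth_frame",
    "example_panel",
]

#: Nominal achiral calibrant concentrations (ug/L); chiral analytes are run
#: at half of each value per enantiomer so the enantiomer sum spans the
#: same range.  0 is the calibration blank.
DEFAULT_CALIBRATION_LEVELS: tuple[float, ...] = (
    0.0, 0.01, 0.05, 0.1, 0.5, 1.0, 5.0, 10.0,
    25.0, 50.0, 100.0, 200.0, 400.0, 600.0, 800.0, 1000.0,
)

#: Pre-extraction spike concentrations for recovery / method accuracy
#: studies (ug/L in the raw water sample); 0 is the unspiked matrix blank.
DEFAULT_SPIKE_LEVELS: tuple[float, ...] = (0.0, 0.05, 0.5, 2.0)

#: Internal-standard concentration in every calibrant vial (ug/L).
CALIBRANT_ISTD_CONCENTRATION = 100.0

#: Internal-standard concentration spiked into every 50-mL water sample
#: before extraction (50 ng in 50 mL = 1 ug/L); after SPE at CF=100 and
#: full IS recovery this lands at the calibrant IS level of 100 ug/L.
MATRIX_ISTD_CONCENTRATION = 1.0

#: Base width (at 5% of apex height) of a Gaussian peak, in sigma units:
#: 2 * sqrt(2 ln 20) ~= 4.895.
GAUSSIAN_BASE_WIDTH_SIGMA = 2.0 * math.sqrt(2.0 * math.log(20.0))

_GAUSS_HEIGHT = 1.0 / math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class AnalyteSpec:
    """Static properties of one analyte or internal standard.

    ``retention_times`` holds one apex time (minutes) for achiral species
    or two strictly increasing times for the E1/E2 enantiomers of a chiral
    species.  ``response_factor`` is the detector area produced per ug/L of
    vial concentration.  ``istd_name`` optionally pins the assigned
    internal standard; ``deuterated_parent`` names the analyte an internal
    standard is the isotope-labelled analog of.
    """

    name: str
    retention_times: tuple[float, ...]
    is_chiral: bool = False
    peak_sigma: float = 0.02
    response_factor: float = 2000.0
    istd_name: str = ""
    deuterated_parent: str = ""

    def __post_init__(self) -> None:
        rts = tuple(float(t) for t in self.retention_times)
        object.__setattr__(self, "retention_times", rts)
        if any(t <= 0 for t in rts):
            raise ValueError(f"{self.name}: retention times must be positive")
        if self.is_chiral:
            if len(rts) != 2 or not rts[0] < rts[1]:
                raise ValueError(
                    f"{self.name}: chiral analytes need two strictly "
                    "increasing retention times (E1 < E2)")
        elif len(rts) != 1:
            raise ValueError(f"{self.name}: achiral analytes have one retention time")
        if self.peak_sigma <= 0:
            raise ValueError(f"{self.name}: peak_sigma must be > 0")
        if self.response_factor <= 0:
            raise ValueError(f"{self.name}: response_factor must be > 0")

    def channels(self) -> list[tuple[str, str, float]]:
        """(compound_id, enantiomer_label, retention_time) per MRM channel.

        Chiral analytes expose two channels labelled by elution order,
        ``E1-<name>`` and ``E2-<name>``; these labels are positional and
        carry no claim about absolute (R/S) configuration.
        """
        if self.is_chiral:
            return [(f"E1-{self.name}", "E1", self.retention_times[0]),
                    (f"E2-{self.name}", "E2", self.retention_times[1])]
        return [(self.name, "", self.retention_times[0])]

    @property
    def mean_retention(self) -> float:
        return float(np.mean(self.retention_times))


def _per_compound(value, name: str, default: float) -> float:
    if isinstance(value, Mapping):
        return float(value.get(name, default))
    return float(value)


@dataclass(frozen=True)
class MatrixSpec:
    """Matrix-dependent effects applied to every compound in a sample.

    ``recovery_fraction``, ``suppression_percent`` (negative = signal
    enhancement) and ``background_concentration`` (ug/L in the raw sample)
    may each be a scalar applied to all compounds or a per-compound-name
    mapping; compounds absent from a mapping get the stated default.
    """

    matrix_id: str
    recovery_fraction: float | Mapping[str, float] = 1.0
    suppression_percent: float | Mapping[str, float] = 0.0
    background_concentration: float | Mapping[str, float] = 0.0
    noise_sd: float = 200.0

    def __post_init__(self) -> None:
        if self.matrix_id == "mobile_phase":
            for attr, clean in (("recovery_fraction", 1.0),
                                ("suppression_percent", 0.0),
                                ("background_concentration", 0.0)):
                value = getattr(self, attr)
                values = value.values() if isinstance(value, Mapping) else [value]
                if any(v != clean for v in values):
                    raise ValueError(f"mobile_phase requires {attr} = {clean}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def recovery(self, compound: str) -> float:
        r = _per_compound(self.recovery_fraction, compound, 1.0)
        if r < 0 or r > 1.6:
            raise ValueError(f"recovery fraction for {compound} outside [0, 1.6]")
        return r

    def suppression(self, compound: str) -> float:
        return _per_compound(self.suppression_percent, compound, 0.0)

    def background(self, compound: str) -> float:
        b = _per_compound(self.background_concentration, compound, 0.0)
        if b < 0:
            raise ValueError(f"background concentration for {compound} < 0")
        return b

    @classmethod
    def mobile_phase(cls, noise_sd: float = 200.0) -> "MatrixSpec":
        return cls(matrix_id="mobile_phase", noise_sd=noise_sd)


@dataclass(frozen=True)
class StudyDesign:
    """Sampling plan for a full validation study."""

    calibration_levels: tuple[float, ...] = DEFAULT_CALIBRATION_LEVELS
    spike_levels: tuple[float, ...] = DEFAULT_SPIKE_LEVELS
    replicates_per_level: int = 3
    days: int = 2
    seed: int = 0
    concentration_factor: float = 100.0

    def __post_init__(self) -> None:
        levels = tuple(float(x) for x in self.calibration_levels)
        object.__setattr__(self, "calibration_levels", levels)
        object.__setattr__(self, "spike_levels",
                           tuple(float(x) for x in self.spike_levels))
        if any(x < 0 for x in levels):
            raise ValueError("calibration levels must be non-negative")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("calibration levels must be strictly increasing")
        if self.replicates_per_level < 1:
            raise ValueError("replicates_per_level must be >= 1")
        if self.days < 1:
            raise ValueError("days must be >= 1")
        if self.concentration_factor <= 0:
            raise ValueError("concentration_factor must be > 0")


@dataclass(frozen=True)
class Sample:
    """One injected vial: per-channel concentrations plus matrix effects.

    ``vial_concentrations`` maps compound channel ids (``E1-<name>`` /
    ``E2-<name>`` / ``<name>``) to the concentration actually present in
    the reconstituted vial (ug/L); ``suppression`` maps the same ids to the
    signal suppression (%) acting on the instrument response.
    """

    sample_id: str
    matrix_id: str
    kind: str
    vial_concentrations: Mapping[str, float]
    suppression: Mapping[str, float]
    nominal_level: float = 0.0
    day: int = 1
    replicate: int = 1
    true_ef: float | None = None


def _check_panel(analytes: Sequence[AnalyteSpec],
                 istds: Sequence[AnalyteSpec] = ()) -> None:
    if not analytes:
        raise ValueError("analyte list is empty")
    names = [a.name for a in list(analytes) + list(istds)]
    if len(set(names)) != len(names):
        raise ValueError("duplicate analyte names")


def _standard_vial(analytes: Sequence[AnalyteSpec],
                   istds: Sequence[AnalyteSpec],
                   level: float,
                   istd_level: float,
                   ef: float = 0.5) -> dict[str, float]:
    """Vial concentrations for a mobile-phase standard at one nominal level.

    Chiral analytes split the per-analyte total ``level`` into E1/E2 at the
    stated enantiomeric fraction (racemic standards by default), so the
    per-enantiomer concentration at an achiral level L is L/2.
    """
    vial: dict[str, float] = {}
    for a in analytes:
        if a.is_chiral:
            vial[f"E1-{a.name}"] = level * ef
            vial[f"E2-{a.name}"] = level * (1.0 - ef)
        else:
            vial[a.name] = level
    for s in istds:
        for cid, _, _ in s.channels():
            vial[cid] = istd_level
    return vial


def generate_calibration_series(analytes: Sequence[AnalyteSpec],
                                istds: Sequence[AnalyteSpec],
                                design: StudyDesign = StudyDesign(),
                                *,
                                day: int = 1) -> list[Sample]:
    """Mobile-phase calibration series: one sample per level per replicate.

    The default level list is the 17-point series 0-1000 ug/L (achiral)
    with chiral analytes at half of each level per enantiomer, and the
    internal-standard mixture at 100 ug/L in every calibrant including the
    blank.  Ground truth is deterministic; randomness only enters when
    responses are rendered or emitted.
    """
    _check_panel(analytes, istds)
    samples = []
    for level in design.calibration_levels:
        for rep in range(1, design.replicates_per_level + 1):
            samples.append(Sample(
                sample_id=f"cal_L{level:g}_d{day}_r{rep}",
                matrix_id="mobile_phase",
                kind="calibrant",
                vial_concentrations=_standard_vial(
                    analytes, istds, level, CALIBRANT_ISTD_CONCENTRATION),
                suppression={},
                nominal_level=level,
                day=day,
                replicate=rep,
                true_ef=0.5,
            ))
    return samples


def generate_instrument_qc_set(analytes: Sequence[AnalyteSpec],
                               istds: Sequence[AnalyteSpec],
                               levels: Sequence[float] = (10.0, 50.0, 200.0),
                               replicates: int = 3,
                               days: int = 2) -> list[Sample]:
    """Mobile-phase QC injections for instrument accuracy/precision.

    Freshly prepared on each of ``days`` non-sequential days; achiral
    analytes sit at the stated levels, chiral analytes at half per
    enantiomer (racemic standards).
    """
    _check_panel(analytes, istds)
    samples = []
    for d in range(1, days + 1):
        for level in levels:
            for rep in range(1, replicates + 1):
                samples.append(Sample(
                    sample_id=f"qc_L{level:g}_d{d}_r{rep}",
                    matrix_id="mobile_phase",
                    kind="instrument_qc",
                    vial_concentrations=_standard_vial(
                        analytes, istds, level, CALIBRANT_ISTD_CONCENTRATION),
                    suppression={},
                    nominal_level=level,
                    day=d,
                    replicate=rep,
                    true_ef=0.5,
                ))
    return samples


def _matrix_vial(analytes: Sequence[AnalyteSpec],
                 istds: Sequence[AnalyteSpec],
                 matrix: MatrixSpec,
                 spike: float,
                 cf: float,
                 ef: float,
                 with_istd: bool) -> tuple[dict[str, float], dict[str, float]]:
    """Vial concentrations + suppression for a pre-extraction-spiked sample.

    Each channel's vial concentration is
    ``(background + its share of the spike) * recovery * CF``; suppression
    is attached per channel and applied to the instrument response only.
    """
    vial: dict[str, float] = {}
    supp: dict[str, float] = {}
    for a in analytes:
        for cid, label, _ in a.channels():
            share = spike * (ef if label == "E1" else (1.0 - ef)) \
                if a.is_chiral else spike
            sample_conc = matrix.background(cid) + share
            vial[cid] = sample_conc * matrix.recovery(cid) * cf
            supp[cid] = matrix.suppression(cid)
    if with_istd:
        for s in istds:
            for cid, _, _ in s.channels():
                vial[cid] = MATRIX_ISTD_CONCENTRATION * matrix.recovery(cid) * cf
                supp[cid] = matrix.suppression(cid)
    return vial, supp


def generate_spiked_matrix_set(analytes: Sequence[AnalyteSpec],
                               istds: Sequence[AnalyteSpec],
                               matrix: MatrixSpec,
                               spike_levels: Sequence[float] = DEFAULT_SPIKE_LEVELS,
                               replicates: int = 3,
                               *,
                               concentration_factor: float = 100.0,
                               true_ef: float = 0.5,
                               day: int = 1) -> list[Sample]:
    """Pre-extraction spiked matrix samples for recovery / method studies.

    The internal-standard mixture is spiked into every sample before
    extraction (50 ng per 50 mL), so internal standards undergo their own
    recovery and suppression.  Spike level 0 is the unspiked matrix blank.
    """
    _check_panel(analytes, istds)
    samples = []
    for spike in spike_levels:
        if spike < 0:
            raise ValueError("spike levels must be non-negative")
        for rep in range(1, replicates + 1):
            vial, supp = _matrix_vial(analytes, istds, matrix, spike,
                                      concentration_factor, true_ef, True)
            samples.append(Sample(
                sample_id=f"{matrix.matrix_id}_S{spike:g}_d{day}_r{rep}",
                matrix_id=matrix.matrix_id,
                kind="matrix_blank" if spike == 0 else "matrix_spike",
                vial_concentrations=vial,
                suppression=supp,
                nominal_level=spike,
                day=day,
                replicate=rep,
                true_ef=true_ef if any(a.is_chiral for a in analytes) else None,
            ))
    return samples


def generate_signal_suppression_set(analytes: Sequence[AnalyteSpec],
                                    istds: Sequence[AnalyteSpec],
                                    matrix: MatrixSpec,
                                    replicates: int = 3,
                                    *,
                                    spike_vial: float = 100.0,
                                    concentration_factor: float = 100.0) -> list[Sample]:
    """Post-extraction spike experiment for signal suppression.

    Matrix is extracted without analytes or internal standards; 50 ng of
    each (100 ug/L in the 0.5-mL extract) is added after elution.  Matched
    matrix blanks (extract of matrix only) and mobile-phase QCs at the same
    vial concentration complete the area triplets.
    """
    _check_panel(analytes, istds)
    samples = []
    for rep in range(1, replicates + 1):
        spiked: dict[str, float] = {}
        blank: dict[str, float] = {}
        qc: dict[str, float] = {}
        supp: dict[str, float] = {}
        for a in list(analytes) + list(istds):
            for cid, label, _ in a.channels():
                bg_vial = (matrix.background(cid) * matrix.recovery(cid)
                           * concentration_factor)
                share = spike_vial / 2.0 if a.is_chiral else spike_vial
                spiked[cid] = bg_vial + share
                blank[cid] = bg_vial
                qc[cid] = share
                supp[cid] = matrix.suppression(cid)
        mid = matrix.matrix_id
        samples.append(Sample(f"{mid}_ss_r{rep}", mid, "ss_spiked",
                              spiked, supp, spike_vial, 1, rep))
        samples.append(Sample(f"{mid}_ssblank_r{rep}", mid, "ss_blank",
                              blank, supp, 0.0, 1, rep))
        samples.append(Sample(f"{mid}_ssqc_r{rep}", "mobile_phase", "ss_qc",
                              qc, {}, spike_vial, 1, rep))
    return samples


def generate_mobile_phase_qc_set(analytes: Sequence[AnalyteSpec],
                                 istds: Sequence[AnalyteSpec],
                                 vial_levels: Sequence[float],
                                 replicates: int = 3) -> list[Sample]:
    """Mobile-phase standards at arbitrary vial levels (QC_x of the
    absolute-recovery formula)."""
    _check_panel(analytes, istds)
    samples = []
    for level in vial_levels:
        for rep in range(1, replicates + 1):
            samples.append(Sample(
                sample_id=f"qcx_L{level:g}_r{rep}",
                matrix_id="mobile_phase",
                kind="recovery_qc",
                vial_concentrations=_standard_vial(
                    analytes, istds, level, CALIBRANT_ISTD_CONCENTRATION),
                suppression={},
                nominal_level=level,
                replicate=rep,
                true_ef=0.5,
            ))
    return samples


def _expected_area(spec: AnalyteSpec, sample: Sample, cid: str) -> float:
    conc = float(sample.vial_concentrations.get(cid, 0.0))
    ss = float(sample.suppression.get(cid, 0.0))
    return spec.response_factor * conc * (1.0 - ss / 100.0)


def render_chromatogram(sample: Sample,
                        analyte: AnalyteSpec,
                        sampling_interval: float = 0.002,
                        seed: int | np.random.Generator = 0,
                        noise_sd: float = 0.0) -> Trace:
    """Render one analyte's MRM channel of a sample as a noisy trace.

    Intensity is a sum of Gaussian peaks (area = response_factor x vial
    concentration x suppression factor, SD = peak_sigma) plus additive
    baseline noise ~ Normal(0, noise_sd).  The time axis covers every
    retention time +/- 8 peak sigmas.
    """
    if sampling_interval <= 0:
        raise ValueError("sampling_interval must be > 0")
    if sampling_interval >= analyte.peak_sigma:
        raise ValueError("sampling_interval must be finer than peak_sigma")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    rts = analyte.retention_times
    t0 = max(rts[0] - 8.0 * analyte.peak_sigma, 0.0)
    t1 = rts[-1] + 8.0 * analyte.peak_sigma
    times = np.arange(t0, t1 + sampling_interval / 2, sampling_interval)
    intensity = np.zeros_like(times)
    for cid, _, rt in analyte.channels():
        area = _expected_area(analyte, sample, cid)
        if area > 0:
            sigma = analyte.peak_sigma
            intensity += (area / (sigma * math.sqrt(2 * math.pi))
                          * np.exp(-0.5 * ((times - rt) / sigma) ** 2))
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, size=times.size)
    return Trace(times, intensity, channel_id=f"{sample.sample_id}/{analyte.name}")


def emit_peak_table(samples: Sequence[Sample],
                    analytes: Sequence[AnalyteSpec],
                    istds: Sequence[AnalyteSpec] = (),
                    seed: int | np.random.Generator = 0,
                    area_cv: float = 0.05,
                    noise_sd: float | Mapping[str, float] = 200.0,
                    injection_cv: float = 0.0) -> pd.DataFrame:
    """Fast path: draw peak areas directly, bypassing trace rendering.

    Areas are the model expectation times mean-one log-normal noise:
    ``area_cv`` is drawn independently per peak, while ``injection_cv``
    (default off) is a factor shared by every peak of a sample — the
    injection-to-injection variability that internal-standard
    normalisation exists to cancel.  Heights, widths and S/N follow from
    the Gaussian peak shape.  The schema matches the peaks module output
    so downstream stages accept either source.
    """
    if area_cv < 0 or injection_cv < 0:
        raise ValueError("area_cv and injection_cv must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    sln = math.sqrt(math.log1p(area_cv ** 2))
    iln = math.sqrt(math.log1p(injection_cv ** 2))
    rows = []
    for sample in samples:
        shared = math.exp(rng.normal(-0.5 * iln ** 2, iln)) \
            if injection_cv > 0 else 1.0
        for spec in list(analytes) + list(istds):
            for cid, label, rt in spec.channels():
                if cid not in sample.vial_concentrations:
                    continue
                expected = _expected_area(spec, sample, cid)
                noise = math.exp(rng.normal(-0.5 * sln ** 2, sln)) \
                    if (area_cv > 0 and expected > 0) else 1.0
                area = expected * shared * noise
                sigma = spec.peak_sigma
                height = area / (sigma * math.sqrt(2 * math.pi))
                width = GAUSSIAN_BASE_WIDTH_SIGMA * sigma
                mnoise = noise_sd.get(sample.matrix_id, 200.0) \
                    if isinstance(noise_sd, Mapping) else noise_sd
                snr = math.inf if (mnoise == 0 and height > 0) \
                    else (0.0 if mnoise == 0 else height / mnoise)
                rows.append({
                    "sample_id": sample.sample_id,
                    "matrix_id": sample.matrix_id,
                    "kind": sample.kind,
                    "day": sample.day,
                    "replicate": sample.replicate,
                    "nominal_level": sample.nominal_level,
                    "analyte": spec.name,
                    "enantiomer_label": label,
                    "compound": cid,
                    "t_start": rt - width / 2,
                    "t_apex": rt,
                    "t_end": rt + width / 2,
                    "height": height,
                    "area": area,
                    "width_base": width,
                    "snr": snr,
                })
    frame = pd.DataFrame(rows)
    missing = [c for c in PEAK_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise AssertionError(f"peak table schema incomplete: {missing}")
    return frame


def ground_truth_frame(samples: Sequence[Sample],
                       analytes: Sequence[AnalyteSpec]) -> pd.DataFrame:
    """Tidy ground-truth table: one row per (sample, compound channel)."""
    rows = []
    for sample in samples:
        for spec in analytes:
            for cid, label, _ in spec.channels():
                if cid not in sample.vial_concentrations:
                    continue
                rows.append({
                    "sample_id": sample.sample_id,
                    "matrix_id": sample.matrix_id,
                    "kind": sample.kind,
                    "analyte": spec.name,
                    "compound": cid,
                    "enantiomer_label": label,
                    "true_vial_concentration": sample.vial_concentrations[cid],
                    "nominal_level": sample.nominal_level,
                    "true_EF": sample.true_ef if spec.is_chiral else np.nan,
                })
    return pd.DataFrame(rows)


def example_panel() -> tuple[list[AnalyteSpec], list[AnalyteSpec]]:
    """A small representative panel: two achiral analytes, one chiral
    beta-blocker-like analyte, and deuterated internal standards."""
    analytes = [
        AnalyteSpec("carbamazepine", (3.10,), response_factor=2500.0,
                    istd_name="carbamazepine-d10"),
        AnalyteSpec("cocaine", (1.85,), response_factor=3200.0),
        AnalyteSpec("atenolol", (4.20, 4.55), is_chiral=True,
                    response_factor=1800.0, istd_name="atenolol-d7"),
    ]
    istds = [
        AnalyteSpec("carbamazepine-d10", (3.08,), response_factor=2500.0,
                    deuterated_parent="carbamazepine"),
        AnalyteSpec("cocaine-d3", (1.84,), response_factor=3200.0,
                    deuterated_parent="cocaine"),
        AnalyteSpec("atenolol-d7", (4.18, 4.53), is_chiral=True,
                    response_factor=1800.0, deuterated_parent="atenolol"),
    ]
    return analytes, istds
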