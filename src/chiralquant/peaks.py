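"""Chromatographic peak detection, integration and signal-to-noise.

A :class:`Trace` is a single MRM channel: a uniformly sampled time series of
detector intensity.  Peaks are located as local maxima rising above the
baseline noise, bounded where the signal falls to a fixed fraction of the
apex height (or at an intervening local minimum), and integrated by the
trapezoid rule over a straight-line baseline drawn between the two
boundaries.

S/N is defined here as baseline-corrected apex height divided by the robust
standard deviation of the baseline (1.4826 x MAD).  This convention is
stated explicitly because detection and quantification limits gated on
S/N >= 3 and S/N >= 10 depend on it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema

__all__ = [
    "Trace",
    "Peak",
    "estimate_noise",
    "detect_peaks",
    "integrate",
    "signal_to_noise",
    "read_trace_csv",
    "write_trace_csv",
    "peaks_to_frame",
    "PEAK_TABLE_COLUMNS",
]

#: Canonical peak-table schema shared with the simulator's fast path.
PEAK_TABLE_COLUMNS = (
    "sample_id",
    "analyte",
    "enantiomer_label",
    "t_start",
    "t_apex",
    "t_end",
    "height",
    "area",
    "width_base",
    "snr",
)

# Relative tolerance on the uniformity of the time axis.
_STEP_RTOL = 1e-9
# MAD -> SD consistency factor for Gaussian noise.
_MAD_SCALE = 1.4826


@dataclass(frozen=True)
class Trace:
    """Uniformly sampled time-intensity chromatogram for one MRM channel."""

    times: np.ndarray
    intensities: np.ndarray
    channel_id: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        intensities = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "intensities", intensities)
        if times.ndim != 1 or times.size < 2:
            raise ValueError("trace needs at least two time points")
        if times.shape != intensities.shape:
            raise ValueError("times and intensities must have equal length")
        steps = np.diff(times)
        if np.any(steps <= 0):
            raise ValueError("times must be strictly increasing")
        step = steps[0]
        if np.any(np.abs(steps - step) > _STEP_RTOL * max(abs(step), 1.0)):
            raise ValueError("times must be uniformly spaced")

    @property
    def sampling_interval(self) -> float:
        return float(self.times[1] - self.times[0])

    def shifted(self, offset_min: float) -> "Trace":
        """Return a copy with the time axis shifted by ``offset_min``."""
        return replace(self, times=self.times + offset_min)


@dataclass(frozen=True)
class Peak:
    """An integrated chromatographic peak.

    ``height`` is the baseline-corrected apex intensity; ``area`` is in
    detector units x minutes; ``width_base`` is the peak base width
    (t_end - t_start) used by the enantiomeric-resolution formula.
    """

    t_start: float
    t_apex: float
    t_end: float
    height: float
    area: float
    width_base: float
    snr: float

    def __post_init__(self) -> None:
        if not (self.t_start < self.t_apex < self.t_end):
            raise ValueError("require t_start < t_apex < t_end")
        if not math.isclose(self.width_base, self.t_end - self.t_start,
                            rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError("width_base must equal t_end - t_start")
        if self.area < 0 or (self.snr < 0 and not math.isinf(self.snr)):
            raise ValueError("area and snr must be non-negative")


def estimate_noise(trace: Trace,
                   exclusion_windows: Sequence[tuple[float, float]] = ()) -> float:
    """Robust baseline noise SD of a trace.

    Points inside any ``(t_lo, t_hi)`` exclusion window (typically known
    peak regions) are discarded; the SD of the remainder is estimated as
    1.4826 x median absolute deviation, which is insensitive to any peaks
    left in the baseline.
    """
    mask = np.ones(trace.times.size, dtype=bool)
    for lo, hi in exclusion_windows:
        mask &= ~((trace.times >= lo) & (trace.times <= hi))
    baseline = trace.intensities[mask]
    if baseline.size < 20:
        raise ValueError("fewer than 20 baseline points outside exclusion windows")
    mad = np.median(np.abs(baseline - np.median(baseline)))
    return float(_MAD_SCALE * mad)


def _boundary_indices(y: np.ndarray, apex: int, fraction: float) -> tuple[int, int]:
    """Walk outward from the apex to the 5%-of-apex crossing or a local minimum."""
    cutoff = fraction * y[apex]
    left = apex
    while left > 0:
        if y[left] <= cutoff:
            break
        if y[left - 1] > y[left]:  # rising again: local minimum at `left`
            break
        left -= 1
    right = apex
    n = y.size - 1
    while right < n:
        if y[right] <= cutoff:
            break
        if y[right + 1] > y[right]:
            break
        right += 1
    return left, right


def detect_peaks(trace: Trace,
                 noise_sd: float,
                 apex_threshold_multiplier: float = 3.0,
                 boundary_fraction: float = 0.05) -> list[Peak]:
    """Detect, bound and integrate all peaks in a trace.

    Local maxima whose baseline-corrected height reaches
    ``apex_threshold_multiplier x noise_sd`` are kept.  Boundaries sit at
    the nearest samples where intensity falls to ``boundary_fraction`` of
    the apex intensity, or at an intervening local minimum, whichever comes
    first.  Peaks are returned sorted by apex time; an empty list is valid.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    y = trace.intensities
    t = trace.times
    candidates = argrelextrema(y, np.greater_equal, order=1)[0]
    # drop plateau duplicates and flat-trace artefacts
    candidates = [i for i in candidates if 0 < i < y.size - 1 and y[i] > 0]

    peaks: list[Peak] = []
    claimed_until = -1
    for apex in candidates:
        if apex <= claimed_until:
            continue
        lo, hi = _boundary_indices(y, apex, boundary_fraction)
        if lo == apex or hi == apex:
            continue
        baseline_at_apex = y[lo] + (y[hi] - y[lo]) * (t[apex] - t[lo]) / (t[hi] - t[lo])
        height = float(y[apex] - baseline_at_apex)
        if height < apex_threshold_multiplier * noise_sd or height <= 0:
            continue
        area = _integrate_segment(t, y, lo, hi)
        snr = signal_to_noise(height, noise_sd)
        peaks.append(Peak(
            t_start=float(t[lo]),
            t_apex=float(t[apex]),
            t_end=float(t[hi]),
            height=height,
            area=max(area, 0.0),
            width_base=float(t[hi] - t[lo]),
            snr=snr,
        ))
        claimed_until = hi
    peaks.sort(key=lambda p: p.t_apex)
    return peaks


def _integrate_segment(t: np.ndarray, y: np.ndarray, lo: int, hi: int) -> float:
    seg_t = t[lo:hi + 1]
    seg_y = y[lo:hi + 1]
    baseline = np.interp(seg_t, [t[lo], t[hi]], [y[lo], y[hi]])
    return float(np.trapezoid(seg_y - baseline, seg_t))


def integrate(trace: Trace, peak: Peak) -> float:
    """Trapezoidal area of the baseline-corrected signal over the peak span.

    The baseline is the straight line joining the intensities at the peak
    boundaries.
    """
    t = trace.times
    if peak.t_start < t[0] or peak.t_end > t[-1]:
        raise ValueError("peak boundaries fall outside the trace span")
    lo = int(np.searchsorted(t, peak.t_start, side="left"))
    hi = int(np.searchsorted(t, peak.t_end, side="right")) - 1
    return _integrate_segment(t, trace.intensities, lo, hi)


def signal_to_noise(height: float, noise_sd: float) -> float:
    """S/N = baseline-corrected apex height over baseline noise SD.

    Zero noise is reported as ``inf`` (above any threshold) rather than an
    error so that noise-free simulations propagate cleanly.
    """
    if height < 0:
        raise ValueError("height must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd == 0:
        return math.inf if height > 0 else 0.0
    return height / noise_sd


def signal_to_noise_peak(peak: Peak, noise_sd: float) -> float:
    """Convenience overload of :func:`signal_to_noise` taking a Peak."""
    return signal_to_noise(peak.height, noise_sd)


def read_trace_csv(path) -> Trace:
    """Read a two-column (time_min, intensity) CSV trace."""
    frame = pd.read_csv(path)
    cols = list(frame.columns)
    return Trace(frame[cols[0]].to_numpy(float), frame[cols[1]].to_numpy(float),
                 channel_id=str(cols[1]))


def write_trace_csv(trace: Trace, path) -> None:
    pd.DataFrame({"time_min": trace.times, "intensity": trace.intensities}).to_csv(
        path, index=False)


def peaks_to_frame(peaks: Iterable[Peak],
                   sample_id: str = "",
                   analyte: str = "",
                   enantiomer_label: str = "") -> pd.DataFrame:
    """Render detected peaks in the canonical peak-table schema."""
    rows = [{
        "sample_id": sample_id,
        "analyte": analyte,
        "enantiomer_label": enantiomer_label,
        "t_start": p.t_start,
        "t_apex": p.t_apex,
        "t_end": p.t_end,
        "height": p.height,
        "area": p.area,
        "width_base": p.width_base,
        "snr": p.snr,
    } for p in peaks]
    return pd.DataFrame(rows, columns=list(PEAK_TABLE_COLUMNS))
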