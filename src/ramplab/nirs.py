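"""Muscle-oxygen-saturation (SmO2) landmark extraction.

During an incremental ramp test the NIRS-derived SmO2 of the working
muscle falls from its resting baseline to a minimum near exhaustion
(deoxygenation: O2 extraction outpaces delivery) and then recovers,
typically overshooting the baseline, during seated rest
(reoxygenation). This module filters the raw SmO2 trace and extracts
the standard landmark set:

========================  =====================================================
``baseline_pct``          mean SmO2 of the 3-min pre-exercise rest
``min_pct``, ``t_deoxy_s``  last local minimum of the filtered signal before
                          reoxygenation, and its time from ramp start
``delta_deoxy_pct``       baseline - min (deoxygenation amplitude)
``slope_deoxy_pct_per_min``  delta_deoxy over t_deoxy
``max_pct``               highest filtered SmO2 within the 8-min recovery
``half_level_pct``        min + (max - min)/2 (half-reoxygenation level)
``delta_half_pct``        half_level - min
``t_half_s``              time from the minimum to the first crossing of the
                          half-reoxygenation level
``slope_half_pct_per_min``  delta_half over t_half
``overshoot_pct``         max - baseline
========================  =====================================================

Raw SmO2 is low-pass filtered with a second-order zero-phase Butterworth
filter (cut-off 0.03 Hz) before any landmark is measured, so no landmark
time is phase-shifted by the filtering itself.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.signal import butter, filtfilt

from .protocol import RampProtocol
from .trace import Trace

__all__ = [
    "DegenerateSignalWarning",
    "SmO2Features",
    "lowpass_filter",
    "compute_baseline",
    "find_smo2_min",
    "compute_features",
]

log = logging.getLogger(__name__)


class DegenerateSignalWarning(UserWarning):
    """Raised when a trace carries no usable kinetic structure (e.g. flat)."""


@dataclass
class SmO2Features:
    """The eleven SmO2 landmarks of a ramp test.

    ``t_half_s`` and ``slope_half_pct_per_min`` are ``None`` when the
    filtered signal never reaches the half-reoxygenation level during
    recovery.
    """

    baseline_pct: float
    min_pct: float
    delta_deoxy_pct: float
    t_deoxy_s: float
    slope_deoxy_pct_per_min: Optional[float]
    max_pct: float
    half_level_pct: float
    delta_half_pct: float
    t_half_s: Optional[float]
    slope_half_pct_per_min: Optional[float]
    overshoot_pct: float

    def to_dict(self) -> dict:
        return {
            "baseline_pct": self.baseline_pct,
            "min_pct": self.min_pct,
            "delta_deoxy_pct": self.delta_deoxy_pct,
            "t_deoxy_s": self.t_deoxy_s,
            "slope_deoxy_pct_per_min": self.slope_deoxy_pct_per_min,
            "max_pct": self.max_pct,
            "half_level_pct": self.half_level_pct,
            "delta_half_pct": self.delta_half_pct,
            "t_half_s": self.t_half_s,
            "slope_half_pct_per_min": self.slope_half_pct_per_min,
            "overshoot_pct": self.overshoot_pct,
        }


def lowpass_filter(trace: Trace, cutoff_hz: float = 0.03,
                   order: int = 2) -> Trace:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    The filter is applied once forward and once backward
    (:func:`scipy.signal.filtfilt`), which cancels the phase response:
    landmark times measured on the output are not delayed. The magnitude
    response is applied twice, so the gain at the cut-off frequency is
    (1/sqrt(2))**2 = 0.5.

    The record edges are padded by reflection over at least three times
    the filter's characteristic time 1/cutoff before filtering, so that
    the 3-min rest window at the start of the record is usable.
    """
    if not trace.is_uniform():
        raise ValueError(
            "lowpass_filter requires a uniformly sampled trace; "
            "resample first (Trace.resample)"
        )
    fs = trace.sample_rate_hz
    nyquist = fs / 2.0
    if cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff_hz ({cutoff_hz}) must be below the Nyquist "
            f"frequency ({nyquist})"
        )
    if order < 1:
        raise ValueError("order must be >= 1")
    b, a = butter(order, cutoff_hz, btype="low", fs=fs)
    padlen = min(len(trace) - 1, int(np.ceil(3.0 * fs / cutoff_hz)))
    filtered = filtfilt(b, a, trace.values, padtype="even", padlen=padlen)
    return replace(trace, values=filtered)


def compute_baseline(trace: Trace, pre_rest_s: float = 180.0) -> float:
    """Mean SmO2 over the pre-exercise rest window [-pre_rest_s, 0)."""
    mask = (trace.times >= -pre_rest_s) & (trace.times < 0)
    if not mask.any():
        raise ValueError(
            f"no samples in the pre-rest window [-{pre_rest_s}, 0)"
        )
    return float(trace.values[mask].mean())


def _local_minima(values: np.ndarray) -> np.ndarray:
    """Indices i with v[i-1] > v[i] <= v[i+1] (earliest index of a plateau)."""
    v = values
    return np.flatnonzero((v[:-2] > v[1:-1]) & (v[1:-1] <= v[2:])) + 1


def _reoxygenation_onset(times: np.ndarray, values: np.ndarray,
                         start: float, rise_s: float, fs: float,
                         min_rise: float) -> Optional[int]:
    """Index of the first sample at/after ``start`` followed by a strict
    rise lasting at least ``rise_s`` seconds and gaining at least
    ``min_rise`` signal units over it; None if there is none.

    The amplitude condition keeps slow upward wander of the filtered
    noise from masquerading as reoxygenation: genuine post-exercise
    reoxygenation gains tens of %SmO2 in its first half minute, while
    residual noise after the 0.03 Hz filter wanders by well under 1 %.
    """
    k = int(np.ceil(rise_s * fs))
    first = int(np.searchsorted(times, start))
    if k == 0:
        return first
    rising = np.diff(values) > 0
    # run[i] == k  <=>  all k diffs starting at i are rising
    runs = np.convolve(rising.astype(int), np.ones(k, dtype=int), "valid")
    ok = np.flatnonzero(runs == k)
    ok = ok[ok >= first]
    for i in ok:
        if values[i + k] - values[i] >= min_rise:
            return int(i)
    return None


def find_smo2_min(trace: Trace, exhaustion_time_s: float,
                  onset_rise_s: float = 30.0,
                  onset_min_rise_pct: float = 2.0) -> tuple[float, float]:
    """Locate the exercise SmO2 minimum on a *filtered* trace.

    Reoxygenation onset is the first time at/after ramp start (t = 0)
    from which the signal rises strictly for at least ``onset_rise_s``
    consecutive seconds, gaining at least ``onset_min_rise_pct`` %SmO2
    over that window. The landmark returned is the last local minimum
    (``v[i-1] > v[i] <= v[i+1]``) at or before that onset; if no local
    minimum exists, the global minimum over [ramp start, onset] is used.

    Returns ``(min_pct, t_min_s)``.
    """
    t0, t1 = trace.span
    if not (t0 <= exhaustion_time_s <= t1):
        raise ValueError(
            f"exhaustion_time_s ({exhaustion_time_s}) outside the trace "
            f"span [{t0}, {t1}]"
        )
    fs = trace.sample_rate_hz
    start_idx = int(np.searchsorted(trace.times, 0.0))
    if start_idx >= len(trace) - 1:
        raise ValueError("trace ends before the ramp start (t = 0)")

    search_vals = trace.values[start_idx:]
    if np.ptp(search_vals) == 0:
        warnings.warn(
            "flat SmO2 signal: returning the first sample after ramp start",
            DegenerateSignalWarning,
        )
        return float(trace.values[start_idx]), float(trace.times[start_idx])

    onset = _reoxygenation_onset(trace.times, trace.values, 0.0,
                                 onset_rise_s, fs, onset_min_rise_pct)
    end_idx = onset if onset is not None else len(trace) - 1

    minima = _local_minima(trace.values)
    minima = minima[(minima >= start_idx) & (minima <= end_idx)]
    if len(minima):
        i = int(minima[-1])
    else:
        seg = trace.values[start_idx:end_idx + 1]
        i = start_idx + int(np.argmin(seg))
    return float(trace.values[i]), float(trace.times[i])


def _first_crossing(times: np.ndarray, values: np.ndarray,
                    after_idx: int, level: float) -> Optional[float]:
    """Time of the first upward crossing of ``level`` after ``after_idx``,
    linearly interpolated between the bracketing samples."""
    v = values
    for j in range(after_idx + 1, len(v)):
        if v[j] >= level:
            if v[j - 1] >= level or v[j] == v[j - 1]:
                return float(times[j])
            frac = (level - v[j - 1]) / (v[j] - v[j - 1])
            return float(times[j - 1] + frac * (times[j] - times[j - 1]))
    return None


def compute_features(trace: Trace, protocol: RampProtocol,
                     exhaustion_time_s: float, *,
                     cutoff_hz: float = 0.03, order: int = 2,
                     onset_rise_s: float = 30.0,
                     onset_min_rise_pct: float = 2.0,
                     resample_hz: float = 1.0) -> SmO2Features:
    """Filter a raw SmO2 trace and extract all landmarks.

    The trace must cover the pre-exercise rest through the post-exercise
    recovery. Non-uniformly sampled input is linearly resampled to
    ``resample_hz`` before filtering (logged). The recovery maximum is
    searched strictly after exhaustion, within the protocol's post-rest
    window.
    """
    if not trace.is_uniform():
        log.info("resampling non-uniform SmO2 trace to %.3g Hz", resample_hz)
        trace = trace.resample(resample_hz)
    filt = lowpass_filter(trace, cutoff_hz=cutoff_hz, order=order)

    baseline = compute_baseline(filt, protocol.pre_rest_s)
    min_pct, t_min = find_smo2_min(filt, exhaustion_time_s,
                                   onset_rise_s=onset_rise_s,
                                   onset_min_rise_pct=onset_min_rise_pct)

    post = (filt.times > exhaustion_time_s) & \
           (filt.times <= exhaustion_time_s + protocol.post_rest_s)
    if not post.any():
        raise ValueError("trace has no samples in the post-rest window")
    max_pct = float(filt.values[post].max())

    delta_deoxy = baseline - min_pct
    half_level = min_pct + 0.5 * (max_pct - min_pct)
    delta_half = half_level - min_pct
    overshoot = max_pct - baseline

    slope_deoxy = delta_deoxy / (t_min / 60.0) if t_min > 0 else None

    i_min = int(np.searchsorted(filt.times, t_min))
    t_cross = _first_crossing(filt.times, filt.values, i_min, half_level)
    if t_cross is None or max_pct <= min_pct:
        t_half = None
        slope_half = None
    else:
        t_half = t_cross - t_min
        slope_half = delta_half / (t_half / 60.0) if t_half > 0 else None

    return SmO2Features(
        baseline_pct=baseline,
        min_pct=min_pct,
        delta_deoxy_pct=delta_deoxy,
        t_deoxy_s=t_min,
        slope_deoxy_pct_per_min=slope_deoxy,
        max_pct=max_pct,
        half_level_pct=half_level,
        delta_half_pct=delta_half,
        t_half_s=t_half,
        slope_half_pct_per_min=slope_half,
        overshoot_pct=overshoot,
    )
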