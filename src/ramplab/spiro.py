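"""Cardiorespiratory peak extraction from the ramp test.

Peak definitions follow standard spiroergometry practice: VO2peak is
the highest 30-s moving average of oxygen uptake, HRpeak the highest
5-s moving average of heart rate, Ppeak the ergometer power of the
stage in progress at exhaustion, and blood-lactate / blood-pressure
peaks are the largest of the discrete 2-minute samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .protocol import RampProtocol
from .session import BL, DBP, HR, SBP, VO2, RampSession
from .trace import Trace

__all__ = [
    "CardioPeaks",
    "vo2_peak",
    "hr_peak",
    "p_peak",
    "discrete_peak",
    "extract_peaks",
]


@dataclass
class CardioPeaks:
    """Peak cardiorespiratory parameters of one ramp test."""

    vo2peak_Lmin: float
    vo2peak_rel_mLkgmin: float
    ppeak_W: float
    hrpeak_bpm: float
    sbp_peak_mmHg: float
    dbp_peak_mmHg: float
    blpeak_mmolL: float

    def to_dict(self) -> dict:
        return {
            "vo2peak_Lmin": self.vo2peak_Lmin,
            "vo2peak_rel_mLkgmin": self.vo2peak_rel_mLkgmin,
            "ppeak_W": self.ppeak_W,
            "hrpeak_bpm": self.hrpeak_bpm,
            "sbp_peak_mmHg": self.sbp_peak_mmHg,
            "dbp_peak_mmHg": self.dbp_peak_mmHg,
            "blpeak_mmolL": self.blpeak_mmolL,
        }


def _max_window_mean(trace: Trace, window_s: float,
                     resample_hz: float = 1.0) -> float:
    """Highest mean over all contiguous windows of ``window_s`` seconds.

    The trace is linearly resampled to a uniform grid if needed; a
    window is N = round(window_s * fs) consecutive samples, each sample
    covering 1/fs s, so every window spans exactly ``window_s`` seconds
    of signal. Windows slide sample by sample.
    """
    t0, t1 = trace.span
    if t1 - t0 < window_s:
        raise ValueError(
            f"trace spans {t1 - t0:.1f} s, shorter than the "
            f"{window_s:.0f}-s averaging window"
        )
    if not trace.is_uniform():
        trace = trace.resample(resample_hz)
    fs = trace.sample_rate_hz
    n = int(round(window_s * fs))
    n = max(n, 1)
    kernel = np.ones(n) / n
    means = np.convolve(trace.values, kernel, mode="valid")
    return float(means.max())


def vo2_peak(trace: Trace) -> float:
    """Highest 30-s average oxygen uptake (L/min)."""
    return _max_window_mean(trace, 30.0)


def hr_peak(trace: Trace) -> float:
    """Highest 5-s average heart rate (bpm)."""
    return _max_window_mean(trace, 5.0)


def p_peak(protocol: RampProtocol, exhaustion_time_s: float) -> float:
    """Peak aerobic power: power of the stage in progress at exhaustion.

    ``p0 + dp * floor(t_exh / step)`` — the stage convention keeps the
    result on the ergometer's 5-W grid.
    """
    if exhaustion_time_s < 0:
        raise ValueError("exhaustion_time_s must be non-negative")
    return float(protocol.p0_W
                 + protocol.dp_W * np.floor(exhaustion_time_s
                                            / protocol.step_s))


def discrete_peak(samples: Sequence[tuple[float, float]]) -> float:
    """Largest value of a discretely sampled channel (e.g. lactate, BP)."""
    samples = list(samples)
    if not samples:
        raise ValueError("discrete_peak needs at least one sample")
    return float(max(v for _, v in samples))


def extract_peaks(session: RampSession,
                  body_mass_kg: float | None = None) -> CardioPeaks:
    """Assemble all cardiorespiratory peaks of a session.

    ``body_mass_kg`` defaults to the session metadata. Raises a KeyError
    naming the channel if a required channel is absent.
    """
    mass = session.body_mass_kg if body_mass_kg is None else body_mass_kg
    if mass <= 0:
        raise ValueError("body mass must be strictly positive")

    vo2 = vo2_peak(session.trace(VO2))
    hr = hr_peak(session.trace(HR))
    pw = p_peak(session.protocol, session.exhaustion_time_s)

    def _peak(channel: str) -> float:
        samples = session.discrete_samples(channel)
        if not samples:
            raise KeyError(
                f"session has no discrete samples for channel '{channel}'"
            )
        return discrete_peak(samples)

    return CardioPeaks(
        vo2peak_Lmin=vo2,
        vo2peak_rel_mLkgmin=1000.0 * vo2 / mass,
        ppeak_W=pw,
        hrpeak_bpm=hr,
        sbp_peak_mmHg=_peak(SBP),
        dbp_peak_mmHg=_peak(DBP),
        blpeak_mmolL=_peak(BL),
    )
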