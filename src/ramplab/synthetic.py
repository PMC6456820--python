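"""Synthetic ramp-test sessions with analytically known landmarks.

The generator emulates one incremental ramp test: 3-min seated rest,
ramp from 25 W in 5-W/20-s stages to volitional exhaustion, 8-min
seated recovery. Channel models:

* **SmO2** — constant baseline at rest; smooth logistic decline from
  baseline to ``min_smo2``, reaching the minimum at ``t_min_offset_s``
  (by default the moment of exhaustion, with the decline still in
  progress, so the minimum is a V-shaped kink as in real recordings);
  then mono-exponential reoxygenation
  ``min + (max - min) * (1 - exp(-dt / tau))`` with overshoot above
  baseline.
* **VO2 / HR** — affine in the ergometer stage power with zero lag,
  frozen at their exhaustion value during recovery.
* **Blood lactate** — quadratic rise from ``bl_rest`` to ``bl_peak``,
  sampled on the 2-minute grid plus a final sample at exhaustion.
* **Blood pressure** — linear rise, sampled on the same grid.

i.i.d. Gaussian noise is added per sample. ``noise_sd`` is expressed in
SmO2 percentage points; every other channel receives noise scaled by
the ratio of its dynamic range to the SmO2 deoxygenation amplitude, so
one parameter sets a comparable relative noise level everywhere. SmO2
is clipped to [0, 100] after noise. Identical seeds give bit-identical
sessions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .nirs import SmO2Features
from .protocol import RampProtocol
from .session import BL, DBP, HR, SBP, SMO2, VO2, RampSession, _UNITS
from .spiro import CardioPeaks, p_peak
from .trace import Trace

__all__ = ["KineticsParams", "GroundTruth", "simulate_session"]


@dataclass
class KineticsParams:
    """Physiological parameters of one simulated ramp test.

    SmO2 values are percentages, times seconds, rates in the units the
    field names state. ``t_min_offset_s`` (time of the SmO2 minimum,
    from ramp start) defaults to ``exhaustion_time_s``.
    """

    baseline_smo2: float = 65.0
    min_smo2: float = 30.0
    max_smo2: float = 70.0
    t_min_offset_s: Optional[float] = None
    decline_width_s: float = 75.0       # logistic steepness of the decline
    decline_mid_frac: float = 0.75      # midpoint of the decline, as a
                                        # fraction of t_min_offset_s
    reoxy_tau_s: float = 30.0
    vo2_rest_Lmin: float = 0.30
    vo2_gain_LminPerW: float = 0.0103   # ~10.3 mL/min/W cycling economy
    hr_rest_bpm: float = 70.0
    hr_gain_bpmPerW: float = 0.5
    bl_rest_mmolL: float = 1.0
    bl_peak_mmolL: float = 8.0
    sbp_rest_mmHg: float = 120.0
    sbp_peak_mmHg: float = 185.0
    dbp_rest_mmHg: float = 80.0
    dbp_peak_mmHg: float = 90.0
    noise_sd: float = 1.0               # SmO2 percentage points
    exhaustion_time_s: float = 500.0
    sample_rate_hz: float = 1.0
    body_mass_kg: float = 92.8

    def __post_init__(self) -> None:
        if self.t_min_offset_s is None:
            self.t_min_offset_s = self.exhaustion_time_s
        checks = [
            (0 <= self.min_smo2, "min_smo2 must be >= 0"),
            (self.min_smo2 < self.baseline_smo2,
             "min_smo2 must be below baseline_smo2"),
            (self.baseline_smo2 <= 100, "baseline_smo2 must be <= 100"),
            (self.min_smo2 < self.max_smo2,
             "min_smo2 must be below max_smo2"),
            (self.max_smo2 <= 100, "max_smo2 must be <= 100"),
            (self.reoxy_tau_s > 0, "reoxy_tau_s must be strictly positive"),
            (self.exhaustion_time_s > 0,
             "exhaustion_time_s must be strictly positive"),
            (self.noise_sd >= 0, "noise_sd must be non-negative"),
            (self.t_min_offset_s > 0,
             "t_min_offset_s must be strictly positive"),
            (self.decline_width_s > 0,
             "decline_width_s must be strictly positive"),
            (0 < self.decline_mid_frac < 1,
             "decline_mid_frac must lie in (0, 1)"),
            (self.sample_rate_hz > 0,
             "sample_rate_hz must be strictly positive"),
            (self.body_mass_kg > 0,
             "body_mass_kg must be strictly positive"),
        ]
        for ok, message in checks:
            if not ok:
                raise ValueError(message)


@dataclass
class GroundTruth:
    """Landmarks implied analytically by the kinetics parameters."""

    features: SmO2Features
    peaks: CardioPeaks


def _smo2_ideal(t: np.ndarray, p: KineticsParams) -> np.ndarray:
    """Noise-free SmO2 trajectory at times ``t`` (seconds from ramp start)."""
    t_min = p.t_min_offset_s
    mid = p.decline_mid_frac * t_min
    w = p.decline_width_s
    lo = expit((0.0 - mid) / w)
    hi = expit((t_min - mid) / w)
    frac = (expit((t - mid) / w) - lo) / (hi - lo)

    out = np.full_like(t, p.baseline_smo2, dtype=float)
    decline = (t >= 0) & (t <= t_min)
    out[decline] = p.baseline_smo2 \
        - (p.baseline_smo2 - p.min_smo2) * frac[decline]
    rec = t > t_min
    out[rec] = p.min_smo2 + (p.max_smo2 - p.min_smo2) * (
        1.0 - np.exp(-(t[rec] - t_min) / p.reoxy_tau_s))
    return out


def _ground_truth(p: KineticsParams, protocol: RampProtocol) -> GroundTruth:
    """Closed-form landmark values for the noise-free trajectory."""
    t_min = float(p.t_min_offset_s)
    delta_deoxy = p.baseline_smo2 - p.min_smo2

    # highest SmO2 reachable inside the post-exhaustion search window
    window_end = p.exhaustion_time_s + protocol.post_rest_s
    true_max = p.min_smo2 + (p.max_smo2 - p.min_smo2) * (
        1.0 - math.exp(-(window_end - t_min) / p.reoxy_tau_s))
    half_level = p.min_smo2 + 0.5 * (true_max - p.min_smo2)
    delta_half = half_level - p.min_smo2
    # recovery crosses the half level at t_min - tau*ln(1 - delta/(max-min))
    t_half = -p.reoxy_tau_s * math.log(
        1.0 - delta_half / (p.max_smo2 - p.min_smo2))

    features = SmO2Features(
        baseline_pct=p.baseline_smo2,
        min_pct=p.min_smo2,
        delta_deoxy_pct=delta_deoxy,
        t_deoxy_s=t_min,
        slope_deoxy_pct_per_min=delta_deoxy / (t_min / 60.0),
        max_pct=true_max,
        half_level_pct=half_level,
        delta_half_pct=delta_half,
        t_half_s=t_half,
        slope_half_pct_per_min=delta_half / (t_half / 60.0),
        overshoot_pct=true_max - p.baseline_smo2,
    )

    ppeak = p_peak(protocol, p.exhaustion_time_s)
    vo2 = p.vo2_rest_Lmin + p.vo2_gain_LminPerW * ppeak
    peaks = CardioPeaks(
        vo2peak_Lmin=vo2,
        vo2peak_rel_mLkgmin=1000.0 * vo2 / p.body_mass_kg,
        ppeak_W=ppeak,
        hrpeak_bpm=p.hr_rest_bpm + p.hr_gain_bpmPerW * ppeak,
        sbp_peak_mmHg=p.sbp_peak_mmHg,
        dbp_peak_mmHg=p.dbp_peak_mmHg,
        blpeak_mmolL=p.bl_peak_mmolL,
    )
    return GroundTruth(features=features, peaks=peaks)


def _discrete_grid(exhaustion_time_s: float) -> np.ndarray:
    """The 2-minute sampling grid, with a final sample at exhaustion."""
    grid = np.arange(0.0, exhaustion_time_s, 120.0)
    return np.append(grid, exhaustion_time_s)


def simulate_session(params: KineticsParams,
                     protocol: RampProtocol | None = None,
                     seed: int = 0) -> tuple[RampSession, GroundTruth]:
    """Simulate one ramp test; returns the session and its ground truth."""
    p = params
    protocol = protocol or RampProtocol()
    fs = p.sample_rate_hz
    n = int(round((protocol.pre_rest_s + p.exhaustion_time_s
                   + protocol.post_rest_s) * fs)) + 1
    t = -protocol.pre_rest_s + np.arange(n) / fs

    rng = np.random.default_rng(seed)
    span_smo2 = p.baseline_smo2 - p.min_smo2  # reference dynamic range

    def noisy(ideal: np.ndarray, channel_span: float) -> np.ndarray:
        if p.noise_sd == 0:
            return ideal.copy()
        sd = p.noise_sd * channel_span / span_smo2
        return ideal + rng.normal(0.0, sd, size=ideal.shape)

    smo2 = noisy(_smo2_ideal(t, p), span_smo2)
    np.clip(smo2, 0.0, 100.0, out=smo2)

    # VO2/HR track stage power with zero lag and hold their exhaustion value
    power = protocol.stage_power(np.minimum(t, p.exhaustion_time_s))
    frozen = protocol.stage_power(p.exhaustion_time_s)
    vo2_ideal = p.vo2_rest_Lmin + p.vo2_gain_LminPerW * power
    hr_ideal = p.hr_rest_bpm + p.hr_gain_bpmPerW * power
    vo2 = noisy(vo2_ideal, p.vo2_gain_LminPerW * frozen)
    hr = noisy(hr_ideal, p.hr_gain_bpmPerW * frozen)

    traces = {
        SMO2: Trace(t, smo2, channel=SMO2, units=_UNITS[SMO2]),
        VO2: Trace(t, vo2, channel=VO2, units=_UNITS[VO2]),
        HR: Trace(t, hr, channel=HR, units=_UNITS[HR]),
    }

    grid = _discrete_grid(p.exhaustion_time_s)
    frac = grid / p.exhaustion_time_s
    rows = []
    for channel, ideal, span in (
        (BL, p.bl_rest_mmolL
             + (p.bl_peak_mmolL - p.bl_rest_mmolL) * frac**2,
         p.bl_peak_mmolL - p.bl_rest_mmolL),
        (SBP, p.sbp_rest_mmHg
              + (p.sbp_peak_mmHg - p.sbp_rest_mmHg) * frac,
         p.sbp_peak_mmHg - p.sbp_rest_mmHg),
        (DBP, p.dbp_rest_mmHg
              + (p.dbp_peak_mmHg - p.dbp_rest_mmHg) * frac,
         p.dbp_peak_mmHg - p.dbp_rest_mmHg),
    ):
        values = noisy(ideal, span)
        rows.append(pd.DataFrame(
            {"time_s": grid, "value": values, "channel": channel}))
    discrete = pd.concat(rows, ignore_index=True)

    session = RampSession(
        traces=traces,
        discrete=discrete,
        protocol=protocol,
        exhaustion_time_s=p.exhaustion_time_s,
        body_mass_kg=p.body_mass_kg,
        subject="synthetic",
    )
    return session, _ground_truth(p, protocol)
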