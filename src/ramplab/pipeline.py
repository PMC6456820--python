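"""End-to-end analysis of one ramp-test session."""

from __future__ import annotations

from typing import Optional

from .nirs import SmO2Features, compute_features
from .session import SMO2, RampSession
from .spiro import CardioPeaks, extract_peaks

__all__ = ["analyze_session", "flatten_parameters", "PARAMETER_GROUPS"]

#: instrument grouping of every extracted parameter, for reporting
PARAMETER_GROUPS = {
    "vo2peak_Lmin": "ramp", "vo2peak_rel_mLkgmin": "ramp",
    "ppeak_W": "ramp", "hrpeak_bpm": "ramp",
    "sbp_peak_mmHg": "ramp", "dbp_peak_mmHg": "ramp",
    "blpeak_mmolL": "ramp",
    "baseline_pct": "nirs", "min_pct": "nirs",
    "delta_deoxy_pct": "nirs", "t_deoxy_s": "nirs",
    "slope_deoxy_pct_per_min": "nirs", "max_pct": "nirs",
    "half_level_pct": "nirs", "delta_half_pct": "nirs",
    "t_half_s": "nirs", "slope_half_pct_per_min": "nirs",
    "overshoot_pct": "nirs",
}


def analyze_session(session: RampSession,
                    **feature_kwargs) -> tuple[SmO2Features, CardioPeaks]:
    """SmO2 landmarks and cardiorespiratory peaks of one session."""
    features = compute_features(
        session.trace(SMO2), session.protocol,
        session.exhaustion_time_s, **feature_kwargs)
    peaks = extract_peaks(session)
    return features, peaks


def flatten_parameters(features: SmO2Features,
                       peaks: CardioPeaks) -> dict[str, Optional[float]]:
    """Single flat name -> value mapping over both parameter sets."""
    out: dict[str, Optional[float]] = {}
    out.update(peaks.to_dict())
    out.update(features.to_dict())
    return out
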