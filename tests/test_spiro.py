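"""Cardiorespiratory peak extraction."""

import dataclasses

import numpy as np
import pytest

from ramplab import (
    RampProtocol,
    Trace,
    discrete_peak,
    extract_peaks,
    hr_peak,
    p_peak,
    vo2_peak,
)
from ramplab.session import HR, VO2

from .oracles import brute_force_window_peak


def _trace(times, values, channel="x"):
    return Trace(np.asarray(times, float), np.asarray(values, float),
                 channel=channel)


def test_constant_vo2_peak_is_that_constant():
    t = np.arange(0, 120.0)
    assert vo2_peak(_trace(t, np.full_like(t, 2.0))) == pytest.approx(2.0)


def test_linear_rise_vo2_peak_is_mean_of_final_window():
    # 1 -> 3 L/min over 600 s: the best 30-s window is the last one and
    # its mean is the value at the window midpoint (~2.95 L/min)
    t = np.arange(0, 601.0)
    v = 1.0 + 2.0 * t / 600.0
    peak = vo2_peak(_trace(t, v))
    assert peak == pytest.approx(brute_force_window_peak(v, 1.0, 30.0))
    assert peak == pytest.approx(2.95, abs=0.005)


def test_one_second_hr_spike_is_averaged_over_the_window():
    t = np.arange(0, 60.0)
    v = np.full_like(t, 120.0)
    v[30] = 200.0
    assert hr_peak(_trace(t, v)) == pytest.approx(136.0)  # (200+4*120)/5


@pytest.mark.parametrize("window_fn, window_s", [(vo2_peak, 30.0),
                                                 (hr_peak, 5.0)])
def test_windowed_peaks_equal_brute_force_enumeration(window_fn, window_s,
                                                      rng):
    for _ in range(20):
        n = int(rng.integers(40, 400))
        t = np.arange(0, float(n))
        v = rng.normal(100.0, 15.0, size=n)
        assert window_fn(_trace(t, v)) == pytest.approx(
            brute_force_window_peak(v, 1.0, window_s), rel=1e-12)


def test_windowed_peak_never_below_trace_mean(rng):
    for _ in range(10):
        t = np.arange(0, 200.0)
        v = rng.normal(2.0, 0.5, size=len(t))
        assert vo2_peak(_trace(t, v)) >= v.mean() - 1e-12


def test_short_traces_are_rejected():
    t = np.arange(0, 10.0)
    with pytest.raises(ValueError, match="30"):
        vo2_peak(_trace(t, np.ones_like(t)))
    with pytest.raises(ValueError, match="5"):
        hr_peak(_trace(t[:4], np.ones(4)))


@pytest.mark.parametrize("t_exh, expected_W", [
    (10.0, 25.0),     # still in the first stage
    (500.0, 150.0),   # 25 + 5 * floor(500/20)
    (900.0, 250.0),
])
def test_p_peak_is_the_power_of_the_stage_in_progress(t_exh, expected_W):
    assert p_peak(RampProtocol(), t_exh) == expected_W


def test_p_peak_is_a_right_step_function_of_exhaustion_time():
    protocol = RampProtocol()
    grid = np.arange(0.0, 600.0, 1.0)
    values = [p_peak(protocol, t) for t in grid]
    diffs = np.diff(values)
    assert np.all(diffs >= 0)
    assert set(np.unique(diffs)) <= {0.0, protocol.dp_W}
    with pytest.raises(ValueError):
        p_peak(protocol, -1.0)


def test_discrete_peak_is_the_sample_maximum():
    assert discrete_peak([(0, 1.1), (120, 2.4), (240, 6.0)]) == 6.0
    assert discrete_peak([(0, 3.3)]) == 3.3
    with pytest.raises(ValueError, match="at least one"):
        discrete_peak([])


def test_noiseless_session_peaks_match_ground_truth(noiseless):
    session, truth = noiseless
    peaks = extract_peaks(session)
    for key, expected in truth.peaks.to_dict().items():
        assert peaks.to_dict()[key] == pytest.approx(expected, abs=1e-6), key


def test_relative_vo2peak_uses_body_mass(noiseless):
    session, _ = noiseless
    peaks = extract_peaks(session, body_mass_kg=100.0)
    assert peaks.vo2peak_rel_mLkgmin == pytest.approx(
        1000.0 * peaks.vo2peak_Lmin / 100.0)


def test_missing_channel_error_names_the_channel(noiseless):
    session, _ = noiseless
    traces = {k: v for k, v in session.traces.items() if k != HR}
    broken = dataclasses.replace(session, traces=traces)
    with pytest.raises(KeyError, match="hr_bpm"):
        extract_peaks(broken)
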