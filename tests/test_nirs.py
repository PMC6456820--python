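"""Filtering and SmO2 landmark extraction."""

import dataclasses

import numpy as np
import pytest

from ramplab import (
    DegenerateSignalWarning,
    KineticsParams,
    RampProtocol,
    Trace,
    compute_baseline,
    compute_features,
    find_smo2_min,
    lowpass_filter,
    simulate_session,
)
from ramplab.session import SMO2

from .oracles import brute_force_smo2_min


def _trace(times, values):
    return Trace(np.asarray(times, float), np.asarray(values, float),
                 channel=SMO2, units="%")


# ---------------------------------------------------------------- filter

def test_filter_preserves_dc_level():
    t = np.arange(0, 600.0)
    out = lowpass_filter(_trace(t, np.full_like(t, 70.0)))
    assert np.allclose(out.values, 70.0, atol=1e-9)


@pytest.mark.parametrize("freq_hz, expected_gain, tol", [
    (0.03, 0.5, 0.02),      # cut-off: single-pass 1/sqrt(2), squared
    (0.003, 1.0, 0.005),    # deep passband
])
def test_filter_gain_matches_butterworth_magnitude(freq_hz, expected_gain,
                                                   tol):
    t = np.arange(0, 12000.0)
    y = 50.0 + 10.0 * np.sin(2 * np.pi * freq_hz * t)
    out = lowpass_filter(_trace(t, y))
    mid = out.values[4000:8000]
    amplitude = 0.5 * (mid.max() - mid.min())
    assert amplitude == pytest.approx(10.0 * expected_gain, abs=10.0 * tol)


def test_filter_rejects_non_uniform_sampling():
    t = np.array([0.0, 1.0, 2.0, 4.0, 5.0, 6.0])
    with pytest.raises(ValueError, match="resample"):
        lowpass_filter(_trace(t, np.zeros_like(t)))


def test_filter_rejects_cutoff_at_or_above_nyquist():
    t = np.arange(0, 100.0)
    with pytest.raises(ValueError, match="Nyquist"):
        lowpass_filter(_trace(t, np.zeros_like(t)), cutoff_hz=0.5)


# -------------------------------------------------------------- baseline

def test_baseline_of_constant_rest_is_that_constant():
    t = np.arange(-180.0, 120.0)
    v = np.where(t < 0, 65.0, 40.0)
    assert compute_baseline(_trace(t, v)) == 65.0


def test_baseline_of_alternating_rest_is_the_midpoint():
    t = np.arange(-180.0, 10.0)
    v = np.where(t % 2 == 0, 60.0, 70.0)
    v[t >= 0] = 50.0
    assert compute_baseline(_trace(t, v)) == pytest.approx(65.0)


def test_baseline_requires_rest_samples():
    t = np.arange(0.0, 100.0)
    with pytest.raises(ValueError, match="pre-rest"):
        compute_baseline(_trace(t, np.full_like(t, 65.0)))


# ---------------------------------------------------------- minimum rule

def test_v_shaped_trace_vertex_is_the_minimum():
    t = np.arange(-180.0, 961.0)
    v = np.where(t < 0, 65.0,
                 np.where(t <= 480, 65.0 - (35.0 / 480.0) * t,
                          30.0 + 0.08 * (t - 480)))
    value, time = find_smo2_min(_trace(t, v), exhaustion_time_s=480.0)
    assert (value, time) == (30.0, 480.0)


def test_last_of_several_local_minima_wins():
    # dip to 32 % at 300 s, brief (<30 s) bump, deeper dip to 30 % at 500 s
    t = np.arange(-180.0, 961.0)
    v = np.full_like(t, 65.0)
    seg = (t >= 0) & (t <= 300)
    v[seg] = 65.0 - (33.0 / 300.0) * t[seg]
    seg = (t > 300) & (t <= 320)
    v[seg] = 32.0 + 0.15 * (t[seg] - 300)
    seg = (t > 320) & (t <= 500)
    v[seg] = 35.0 - (5.0 / 180.0) * (t[seg] - 320)
    seg = t > 500
    v[seg] = 30.0 + 0.2 * (t[seg] - 500)
    value, time = find_smo2_min(_trace(t, v), exhaustion_time_s=500.0)
    assert (value, time) == (30.0, 500.0)
    assert brute_force_smo2_min(t, v) == (30.0, 500.0)


def test_minimum_agrees_with_exhaustive_scan_on_random_traces(rng):
    t = np.arange(-60.0, 600.0)
    for _ in range(25):
        steps = rng.normal(-0.05, 0.4, size=len(t))
        v = 60.0 + np.cumsum(steps)
        v = np.convolve(v, np.ones(9) / 9, mode="same")  # smooth a little
        tr = _trace(t, v)
        assert find_smo2_min(tr, 400.0) == brute_force_smo2_min(t, v)


def test_flat_trace_warns_and_returns_first_sample():
    t = np.arange(-60.0, 300.0)
    with pytest.warns(DegenerateSignalWarning):
        value, time = find_smo2_min(_trace(t, np.full_like(t, 55.0)), 200.0)
    assert (value, time) == (55.0, 0.0)


def test_exhaustion_outside_trace_is_rejected(noiseless):
    session, _ = noiseless
    tr = session.trace(SMO2)
    with pytest.raises(ValueError, match="outside"):
        find_smo2_min(lowpass_filter(tr), exhaustion_time_s=5000.0)


# ----------------------------------------------------------- composition

def test_feature_identities_hold_on_noisy_data(make_session):
    session, _ = make_session(seed=11)
    f = compute_features(session.trace(SMO2), session.protocol,
                         session.exhaustion_time_s)
    assert f.delta_deoxy_pct == pytest.approx(
        f.baseline_pct - f.min_pct, abs=1e-12)
    assert f.half_level_pct - f.min_pct == pytest.approx(
        0.5 * (f.max_pct - f.min_pct), abs=1e-12)
    assert f.delta_half_pct == pytest.approx(
        f.half_level_pct - f.min_pct, abs=1e-12)
    assert f.overshoot_pct == pytest.approx(
        f.max_pct - f.baseline_pct, abs=1e-12)
    assert f.slope_deoxy_pct_per_min == pytest.approx(
        f.delta_deoxy_pct / (f.t_deoxy_s / 60.0))
    assert f.slope_half_pct_per_min == pytest.approx(
        f.delta_half_pct / (f.t_half_s / 60.0))


def test_landmark_times_are_shift_equivariant(noiseless):
    session, _ = noiseless
    tr = session.trace(SMO2)
    shift = 37.0  # whole samples, so the value sequence is unchanged
    shifted = dataclasses.replace(tr, times=tr.times + shift)

    base = lowpass_filter(tr)
    moved = lowpass_filter(shifted)
    v0, t0 = find_smo2_min(base, session.exhaustion_time_s)
    v1, t1 = find_smo2_min(moved, session.exhaustion_time_s + shift)
    assert v1 == v0
    assert t1 == t0 + shift


def test_longer_reoxygenation_tau_increases_extracted_half_time():
    previous = -np.inf
    for tau in (15.0, 30.0, 60.0, 120.0):
        session, _ = simulate_session(
            KineticsParams(noise_sd=0.0, reoxy_tau_s=tau), seed=0)
        f = compute_features(session.trace(SMO2), session.protocol,
                             session.exhaustion_time_s)
        assert f.t_half_s > previous
        previous = f.t_half_s


def test_unreachable_half_level_is_flagged_missing():
    # SmO2 declines through the whole record and never reoxygenates
    t = np.arange(-180.0, 981.0)
    v = 65.0 - 0.03 * (t + 180.0)
    f = compute_features(_trace(t, v), RampProtocol(),
                         exhaustion_time_s=500.0)
    assert f.t_half_s is None
    assert f.slope_half_pct_per_min is None
    assert np.isfinite(f.min_pct) and np.isfinite(f.max_pct)


def test_non_uniform_input_is_resampled_before_filtering(noiseless):
    session, _ = noiseless
    tr = session.trace(SMO2)
    jitter = np.linspace(0.0, 0.3, len(tr.times))  # keeps order, non-uniform
    irregular = dataclasses.replace(tr, times=tr.times + jitter)
    f_uniform = compute_features(tr, session.protocol,
                                 session.exhaustion_time_s)
    f_irregular = compute_features(irregular, session.protocol,
                                   session.exhaustion_time_s)
    assert f_irregular.t_deoxy_s == pytest.approx(f_uniform.t_deoxy_s, abs=2.0)
    assert f_irregular.min_pct == pytest.approx(f_uniform.min_pct, abs=0.1)
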