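# Methods

This note documents the models, conventions and numerical choices
behind `ramplab`, and what the synthetic-data validation does and does
not demonstrate.

## Session model

One ramp test is represented on a single time axis: seated rest on
[−180 s, 0), ramp start at t = 0, volitional exhaustion at t_exh,
recovery on (t_exh, t_exh + 480 s]. Continuous channels (SmO₂ %, VO₂
L·min⁻¹, HR bpm) are uniform traces (1 Hz by default); lactate and
blood pressure are discrete samples on a 2-minute grid. The protocol
constants (25 W start, +5 W per 20 s, 3-min pre-rest, 8-min post-rest)
live in `RampProtocol` and everything downstream reads them from there.

## SmO₂ filtering and landmark extraction

Raw SmO₂ is filtered with a second-order Butterworth low-pass at
0.03 Hz applied forward and backward (`scipy.signal.filtfilt`), giving
zero phase lag and a squared magnitude response (gain 0.5 at the
cut-off, not 1/√2). Edges are padded by reflection over 3/0.03 Hz =
100 s so the rest window at the record edge filters cleanly.
Non-uniform input is linearly resampled to 1 Hz first.

*Minimum detection.* Reoxygenation onset is the first time at/after
ramp start from which the filtered signal rises strictly for ≥ 30
consecutive seconds **and gains ≥ 2 %SmO₂ over that window**; the
landmark is the last discrete local minimum (`v[i−1] > v[i] ≤ v[i+1]`,
plateaus take their earliest index) at or before onset, falling back to
the global minimum of [ramp start, onset] when no local minimum exists.
The amplitude condition is part of what "sustained rise" must mean in
practice: residual noise after the 0.03 Hz filter is smooth (sd ≈ 0.2 %
for 1 % raw noise) and its slow upswings regularly last 30 s during the
quasi-flat early ramp, whereas genuine post-exercise reoxygenation
gains tens of %SmO₂ in its first half minute. Without the amplitude
condition the onset fires minutes early on a sizeable fraction of noisy
records; 2 % is ≈ 10 filtered-noise standard deviations yet a small
fraction of any physiological reoxygenation amplitude, and it is
configurable (`onset_min_rise_pct`).

*Half-reoxygenation.* t_½ is measured from the detected minimum to the
first crossing of min + (max − min)/2, with linear interpolation
between the bracketing samples. Slopes are reported in %·min⁻¹ (Δ and t
are both reported too, so any other unit is recomputable). When the
signal never reaches the half level during recovery (e.g. a record that
keeps declining), t_½ and slope_½ are returned as missing rather than
guessed.

### Known bias: filtering a V-shaped minimum

The decline into the minimum and the exponential recovery out of it
meet at a slope discontinuity. Smoothing a kink with a ~5-s-wide
zero-phase kernel (1/(2π·0.03 Hz)) necessarily rounds it: at the
default study conditions the detected minimum sits ≈ 0.3–0.8 %SmO₂
away from the analytic minimum and 8–12 s early, and since the absolute
time of the half-level crossing is recovered accurately, t_½ reads
≈ 10 s long. This is a property of the published filtering convention,
not of the implementation: the bias saturates near 8 s for any
realistic decline steepness (a cliff-steep decline trades it for a
larger value bias). The acceptance suite quantifies it — baseline,
minimum value and minimum time recover within ±0.25 %, ±1.0 % and
±12 s over 100 noisy sessions, while the t_½ checks against analytic
truth fail by the structural ~+10 s and are intentionally left failing
rather than loosened. Comparisons of t_½ *between* sessions processed
with the same convention (the quantity the PRE/POST report uses) are
unaffected to first order, because the bias is common to both sessions.

## Cardiorespiratory peaks

VO₂peak and HR_peak are maxima of N-sample moving means on the 1-Hz
grid with N = round(window/Δt) (30 and 5 samples), so each window
covers exactly the nominal duration; windows slide sample by sample,
and irregular breath-by-breath input is linearly resampled first.
P_peak uses the stage-in-progress convention, p0 + dp·⌊t_exh/step⌋,
which keeps results on the ergometer's 5-W grid; interpolating the ramp
instead would differ by at most one increment and is deliberately not
done. Discrete peaks (lactate, blood pressure) are plain sample maxima.

## Prescription

The CON progression and the 1.4 ECC load multiplier are fixed study
constants. The ECC interval count is reconstructed as
round-half-up(n_CON/multiplier), which reproduces both prescribed
counts (10/1.4 → 7.14 → 7, 15/1.4 → 10.71 → 11) and generalizes to
other multipliers; with 1.4 the weekly ECC/CON external-work ratio is
0.98 (10-interval weeks) or 1.027 (15-interval weeks), within the 5 %
matching band. Loads are reported to 0.1 W; no rounding to
device-settable steps is applied. The two familiarization sessions
before week 1 carry no load prescription and are represented only by
the `FAMILIARIZATION_SESSIONS` constant.

## Synthetic generator

The generator emulates the study conditions, not device firmware:

- **SmO₂**: baseline 65 % at rest; normalized logistic decline to 30 %
  reaching the minimum at exhaustion (midpoint at 0.75·t_min, width
  0.15·t_min ≈ 75 s), so the signal is still falling ≈ 0.1 %·s⁻¹ at the
  minimum — real ramp-test recordings show exactly this V-shaped
  minimum, which is why "last local minimum" detection exists; then
  mono-exponential reoxygenation `min + (max − min)(1 − e^(−Δt/τ))`
  with max 70 % (5 % overshoot) and τ = 30 s.
- **VO₂/HR**: affine in the stage power with zero lag (rest 0.30
  L·min⁻¹ and 70 bpm; gains 10.3 mL·min⁻¹·W⁻¹ — typical cycling
  economy — and 0.5 bpm·W⁻¹), frozen at their exhaustion value during
  recovery. Exhaustion defaults to 500 s, giving P_peak = 150 W and
  VO₂peak ≈ 1.85 L·min⁻¹, a realistic deconditioned-patient test.
- **Lactate**: quadratic rise 1 → 8 mmol·L⁻¹ (lactate accumulates
  super-linearly with ramp intensity), sampled every 2 min plus a final
  sample at exhaustion; blood pressure rises linearly 120/80 → 185/90.
- **Noise**: i.i.d. Gaussian per sample. `noise_sd` is expressed in
  SmO₂ percentage points (default 1 %); every other channel receives
  sd scaled by the ratio of its dynamic range to the SmO₂ deoxygenation
  amplitude, so one parameter sets a comparable relative noise level
  throughout. SmO₂ is clipped to [0, 100] after noise. A fixed seed
  gives bit-identical sessions.

Ground truth is computed in closed form from the parameters (e.g.
t_½ = −τ·ln(1 − Δ_½/(max − min)), which is τ·ln 2 when recovery
completes inside the window).

What the generator does **not** model: breath-by-breath gas-exchange
variability, VO₂/HR on-kinetics (zero lag by default), physiological
autocorrelation of the noise, cardiac drift, or the Moxy monitor's
internal smoothing (its native rate and firmware filtering are not
public). Passing parameter-recovery tests therefore demonstrates the
correctness and noise robustness of the extraction chain under clean
study-shaped signals — not performance on pathological real-world
recordings (sensor detachment, motion artifacts).

## Problem sizes and determinism

The validation suite uses 100 seeded noisy sessions of ~1160 samples
each for parameter recovery, 200 random traces for the windowed-peak
brute-force equivalence and 50 for the minimum-detection scan; the
whole suite runs in a few seconds. All randomness flows through
explicit `numpy.random.default_rng` seeds, and hypothesis runs
derandomized.
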