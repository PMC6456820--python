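"""Simulate a ramp test and write it to disk as plain CSV + YAML.

The synthetic session covers 3 min seated rest, a 25 W + 5 W/20 s ramp
to exhaustion at 500 s (peak stage 150 W), and 8 min of recovery, with
SmO2, VO2 and HR at 1 Hz plus 2-minute lactate and blood-pressure
samples.
"""

import tempfile
from pathlib import Path

from ramplab import KineticsParams, simulate_session, write_session

params = KineticsParams(noise_sd=1.0)  # 1 %SmO2 measurement noise
session, truth = simulate_session(params, seed=42)

out = Path(tempfile.mkdtemp()) / "session"
files = write_session(session, out)

print(f"session written to {out}:")
for f in files:
    print("   ", f.name)
print()
print(f"exhaustion after {session.exhaustion_time_s:.0f} s of ramping")
print(f"analytic ground truth: SmO2 min {truth.features.min_pct:.1f} % "
      f"at t = {truth.features.t_deoxy_s:.0f} s, "
      f"VO2peak {truth.peaks.vo2peak_Lmin:.2f} L/min, "
      f"P_peak {truth.peaks.ppeak_W:.0f} W")
print("(the generator knows these landmarks exactly, so every later")
print(" analysis step can be checked against them)")
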