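"""Aggregate soft-robot power-test attempts.

The Real Power test (simulated squat jump) and Reactive Power test
(simulated countermovement jump) are repeated 4 times per leg against
an external load of half the body mass; the average and peak attempt
power are the reported outcomes.
"""

from ramplab import aggregate_attempts, external_load

body_mass = 92.8  # kg
load = external_load(body_mass)
print(f"body mass {body_mass} kg -> external load {load:.1f} kg per leg")

result = aggregate_attempts(
    [412.0, 431.0, 405.0, 428.0], test_type="real", leg="left",
    external_load_kg=load)
print(f"real power, left leg: avg {result.avg_W:.1f} W, "
      f"peak {result.peak_W:.1f} W "
      f"({'complete' if result.complete else 'incomplete'} test)")

# one attempt did not reach the 90-degree knee-flexion target
partial = aggregate_attempts(
    [398.0, 372.0, 415.0, 402.0], test_type="reactive", leg="right",
    valid=[True, False, True, True], external_load_kg=load)
print(f"reactive power, right leg: avg {partial.avg_W:.1f} W, "
      f"peak {partial.peak_W:.1f} W over {len(partial.attempts_W)} valid "
      f"attempts (flagged incomplete)")
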