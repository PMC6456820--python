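"""Derive the 8-week CON and ECC interval prescriptions from P_peak.

Eccentric pedaling has a lower metabolic cost at the same mechanical
work, so the ECC group trains at 1.4x the concentric load with
proportionally fewer intervals; the weekly external work of the two
programs stays matched within 5 %.
"""

from ramplab import con_schedule, ecc_schedule, work_match_ratio

ppeak = 150.0  # W, from the PRE ramp test
con = con_schedule(ppeak)
ecc = ecc_schedule(ppeak, load_multiplier=1.4)

print(f"P_peak = {ppeak:.0f} W")
print("week   CON load x n      ECC load x n      work ratio ECC/CON")
for c, e in zip(con, ecc):
    ratio = work_match_ratio(e, c)
    print(f"  {c.week}   {c.load_W:6.1f} W x {c.n_intervals:2d}   "
          f"{e.load_W:6.1f} W x {e.n_intervals:2d}      {ratio:.3f}")

print()
print("each interval is 1 min work + 1 min passive rest, 3 sessions per")
print("week; a ratio of 1.000 would be perfect external-work matching.")
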