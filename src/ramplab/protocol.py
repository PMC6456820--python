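"""Ramp-test protocol definition.

The incremental test starts with a 3-minute seated rest, then the
ergometer load begins at 25 W and rises by 5 W every 20 s (15 W/min)
until volitional exhaustion, followed by an 8-minute seated recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RampProtocol"]


@dataclass
class RampProtocol:
    """Timing and load constants of the incremental ramp test."""

    pre_rest_s: float = 180.0   # seated rest before the ramp
    p0_W: float = 25.0          # initial ergometer power
    dp_W: float = 5.0           # power increment per stage
    step_s: float = 20.0        # stage duration
    post_rest_s: float = 480.0  # seated recovery after exhaustion

    def __post_init__(self) -> None:
        for name in ("pre_rest_s", "p0_W", "dp_W", "step_s", "post_rest_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def ramp_rate_W_per_min(self) -> float:
        """Mean rate of load increase (5 W / 20 s -> 15 W/min)."""
        return self.dp_W * 60.0 / self.step_s

    def stage_power(self, t_s):
        """Ergometer power of the stage in progress at time ``t_s``.

        ``t_s`` is seconds from ramp start; before the ramp (t < 0) the
        power is 0 (seated rest). Accepts scalars or arrays.
        """
        t = np.asarray(t_s, dtype=float)
        p = self.p0_W + self.dp_W * np.floor(t / self.step_s)
        p = np.where(t < 0, 0.0, p)
        return float(p) if np.isscalar(t_s) else p
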