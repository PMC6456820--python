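"""Uniformly time-stamped physiological channel data.

A :class:`Trace` holds one channel of a ramp-test session (SmO2, VO2, HR)
on a common time axis: the pre-exercise rest period occupies negative
times, the incremental ramp starts at t = 0 s, and post-exercise recovery
follows volitional exhaustion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Trace"]


@dataclass
class Trace:
    """A single uniformly (or irregularly) sampled channel.

    Parameters
    ----------
    times
        Sample times in seconds from ramp start (rest is negative).
        Must be strictly increasing, length >= 2.
    values
        Sample values in ``units``. Must be finite.
    channel
        Channel label, e.g. ``"smo2_pct"``.
    units
        Physical units of ``values``, e.g. ``"%"``.
    """

    times: np.ndarray
    values: np.ndarray
    channel: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if len(self.times) < 2:
            raise ValueError("a trace needs at least 2 samples")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if not np.all(np.isfinite(self.times)):
            raise ValueError("times must be finite")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def span(self) -> tuple[float, float]:
        """(first, last) sample time in seconds."""
        return float(self.times[0]), float(self.times[-1])

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        """True if consecutive samples are equally spaced (within rtol)."""
        dt = np.diff(self.times)
        return bool(np.allclose(dt, dt[0], rtol=rtol, atol=1e-9))

    @property
    def sample_rate_hz(self) -> float:
        """Sampling rate; only meaningful for uniform traces."""
        if not self.is_uniform():
            raise ValueError(
                "trace is not uniformly sampled; resample it first "
                "(Trace.resample)"
            )
        return 1.0 / float(self.times[1] - self.times[0])

    def resample(self, rate_hz: float) -> "Trace":
        """Linearly interpolate onto a uniform grid at ``rate_hz``.

        The grid starts at the first sample time and ends at or before the
        last one; no extrapolation is performed.
        """
        if rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        t0, t1 = self.span
        n = int(np.floor((t1 - t0) * rate_hz)) + 1
        grid = t0 + np.arange(n) / rate_hz
        vals = np.interp(grid, self.times, self.values)
        return replace(self, times=grid, values=vals)

    def window(self, t_from: float, t_to: float,
               closed: str = "both") -> "Trace":
        """Sub-trace with times in the given interval.

        ``closed`` is one of ``"both"``, ``"left"``, ``"right"``,
        ``"neither"`` and controls endpoint inclusion.
        """
        lo = self.times >= t_from if closed in ("both", "left") else self.times > t_from
        hi = self.times <= t_to if closed in ("both", "right") else self.times < t_to
        mask = lo & hi
        if mask.sum() < 2:
            raise ValueError(
                f"window [{t_from}, {t_to}] contains fewer than 2 samples"
            )
        return replace(self, times=self.times[mask], values=self.values[mask])
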