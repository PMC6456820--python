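"""Soft-robot anaerobic power-test aggregation.

The *Real Power* test (simulated squat jump) and the *Reactive Power*
test (simulated countermovement jump) are performed per leg against an
external load of 50 % body mass per leg, with 4 attempts each; the
average and the peak of the attempts are the reported outcomes.
Attempts are opaque per-attempt power scalars; an attempt is excluded
when its validity flag is False (e.g. the 90-degree knee-flexion target
was not reached).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

__all__ = ["PowerTestResult", "aggregate_attempts", "external_load"]

EXPECTED_ATTEMPTS = 4


@dataclass(frozen=True)
class PowerTestResult:
    """Aggregated outcome of one power test on one leg."""

    test_type: str              # "real" or "reactive"
    leg: str                    # "left" or "right"
    attempts_W: tuple[float, ...]
    avg_W: float
    peak_W: float
    complete: bool              # True iff the expected 4 valid attempts
    external_load_kg: Optional[float] = None


def aggregate_attempts(attempts_W: Sequence[float], test_type: str,
                       leg: str,
                       valid: Sequence[bool] | None = None,
                       external_load_kg: float | None = None
                       ) -> PowerTestResult:
    """Average and peak power over the valid attempts of one test.

    ``valid`` marks attempts to keep (all kept when omitted). Fewer or
    more than 4 valid attempts sets ``complete=False`` but the values
    are still returned.
    """
    attempts = [float(a) for a in attempts_W]
    if valid is not None:
        if len(valid) != len(attempts):
            raise ValueError("valid flags must match attempts in length")
        attempts = [a for a, ok in zip(attempts, valid) if ok]
    if not attempts:
        raise ValueError("no valid attempts to aggregate")
    if not all(math.isfinite(a) for a in attempts):
        raise ValueError("attempts must be finite")
    return PowerTestResult(
        test_type=test_type,
        leg=leg,
        attempts_W=tuple(attempts),
        avg_W=sum(attempts) / len(attempts),
        peak_W=max(attempts),
        complete=len(attempts) == EXPECTED_ATTEMPTS,
        external_load_kg=external_load_kg,
    )


def external_load(body_mass_kg: float) -> float:
    """Per-leg external load of the power tests: 50 % of body mass (kg)."""
    if body_mass_kg <= 0:
        raise ValueError("body_mass_kg must be strictly positive")
    return 0.5 * body_mass_kg
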