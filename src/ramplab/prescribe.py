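"""Work-matched concentric/eccentric interval-training prescription.

The 8-week pedaling-type interval program on the soft robot is derived
from the peak aerobic power (P_peak) of the PRE ramp test. Each
interval is 1 min of work followed by 1 min of passive rest. The
concentric (CON) progression is:

=========  ==============  ==========
weeks      load             intervals
=========  ==============  ==========
1-2        65 % P_peak      10
3-4        65 % P_peak      15
5-6        70 % P_peak      15
7-8        75 % P_peak      15
=========  ==============  ==========

Eccentric (ECC) muscle work has a lower metabolic cost at matched
mechanical work, so the ECC group trains at 1.4x the CON load; to keep
the external work of both groups equal, the interval count is divided
by the same factor and rounded half-up (10 -> 7, 15 -> 11), which
keeps the per-week work ratio within 5 % of unity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PrescriptionWeek",
    "SessionSettings",
    "con_schedule",
    "ecc_schedule",
    "work_match_ratio",
]

#: (load fraction of P_peak, CON interval count) for weeks 1..8
_CON_PROGRESSION = [
    (0.65, 10), (0.65, 10),
    (0.65, 15), (0.65, 15),
    (0.70, 15), (0.70, 15),
    (0.75, 15), (0.75, 15),
]

#: familiarization sessions on the soft robot before week 1 (no load
#: prescription is attached to them)
FAMILIARIZATION_SESSIONS = 2


@dataclass(frozen=True)
class SessionSettings:
    """Fixed constants of every training session."""

    rom_deg: tuple[float, float] = (5.0, 90.0)  # knee flexion range
    cadence_rpm: float = 30.0
    frequency_per_week: int = 3
    min_rest_between_sessions_h: float = 48.0


@dataclass(frozen=True)
class PrescriptionWeek:
    """One week of the interval prescription."""

    week: int                   # 1..8
    mode: str                   # "CON" or "ECC"
    load_fraction: float        # actual fraction of P_peak (ECC includes
                                # the load multiplier)
    load_W: float
    n_intervals: int
    work_interval_s: float = 60.0
    rest_interval_s: float = 60.0

    @property
    def relative_work(self) -> float:
        """Dimensionless weekly work: load fraction x intervals x minutes."""
        return (self.load_fraction * self.n_intervals
                * self.work_interval_s / 60.0)

    @property
    def external_work_J(self) -> float:
        """Mechanical work of one session: load x total work time."""
        return self.load_W * self.n_intervals * self.work_interval_s


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def con_schedule(ppeak_W: float) -> list[PrescriptionWeek]:
    """Concentric 8-week schedule for a given P_peak (watts)."""
    if ppeak_W <= 0:
        raise ValueError("ppeak_W must be strictly positive")
    return [
        PrescriptionWeek(week=i + 1, mode="CON", load_fraction=frac,
                         load_W=frac * ppeak_W, n_intervals=n)
        for i, (frac, n) in enumerate(_CON_PROGRESSION)
    ]


def ecc_schedule(ppeak_W: float,
                 load_multiplier: float = 1.4) -> list[PrescriptionWeek]:
    """Eccentric schedule: CON loads x multiplier, intervals work-matched.

    The interval count is ``round_half_up(n_con / multiplier)``; for the
    study's multiplier of 1.4 this gives 7 (vs 10) and 11 (vs 15).
    """
    if load_multiplier <= 0:
        raise ValueError("load_multiplier must be strictly positive")
    weeks = []
    for con in con_schedule(ppeak_W):
        weeks.append(PrescriptionWeek(
            week=con.week, mode="ECC",
            load_fraction=load_multiplier * con.load_fraction,
            load_W=load_multiplier * con.load_W,
            n_intervals=_round_half_up(con.n_intervals / load_multiplier),
        ))
    return weeks


def work_match_ratio(ecc_week: PrescriptionWeek,
                     con_week: PrescriptionWeek) -> float:
    """ECC / CON external-work ratio for one week (1.0 = perfectly matched)."""
    if ecc_week.week != con_week.week:
        raise ValueError(
            f"weeks differ: ECC week {ecc_week.week} vs "
            f"CON week {con_week.week}"
        )
    denom = con_week.load_W * con_week.n_intervals
    if denom == 0:
        raise ValueError("CON week has zero external work")
    return (ecc_week.load_W * ecc_week.n_intervals) / denom
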