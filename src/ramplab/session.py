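"""Ramp-test session container and on-disk layout.

A session is a directory of plain-text files:

* one ``<channel>.csv`` per continuous channel (columns ``time_s,value``),
* ``discrete.csv`` for the 2-minute samples (``time_s,value,channel``),
* ``session.yaml`` with the protocol constants, exhaustion time, body
  mass and channel units.

Continuous channels use the labels ``smo2_pct`` (%), ``vo2_Lmin``
(L/min) and ``hr_bpm`` (bpm); discrete channels are ``bl_mmolL``
(blood lactate), ``sbp_mmHg`` and ``dbp_mmHg`` (systolic/diastolic
blood pressure). Floats are written with full repr precision, so a
write/read round-trip reproduces the session exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .protocol import RampProtocol
from .trace import Trace

__all__ = ["RampSession", "write_session", "read_session"]

SMO2 = "smo2_pct"
VO2 = "vo2_Lmin"
HR = "hr_bpm"
BL = "bl_mmolL"
SBP = "sbp_mmHg"
DBP = "dbp_mmHg"

_UNITS = {SMO2: "%", VO2: "L/min", HR: "bpm",
          BL: "mmol/L", SBP: "mmHg", DBP: "mmHg"}


@dataclass
class RampSession:
    """All channels and metadata of one ramp test."""

    traces: dict[str, Trace]
    discrete: pd.DataFrame          # columns: time_s, value, channel
    protocol: RampProtocol
    exhaustion_time_s: float
    body_mass_kg: float
    subject: str = "anonymous"

    def __post_init__(self) -> None:
        if self.exhaustion_time_s <= 0:
            raise ValueError("exhaustion_time_s must be strictly positive")
        if self.body_mass_kg <= 0:
            raise ValueError("body_mass_kg must be strictly positive")
        required = {"time_s", "value", "channel"}
        if not required.issubset(self.discrete.columns):
            raise ValueError(
                f"discrete samples need columns {sorted(required)}"
            )

    def trace(self, channel: str) -> Trace:
        """Return a continuous channel, with a clear error if absent."""
        try:
            return self.traces[channel]
        except KeyError:
            raise KeyError(
                f"session is missing the channel '{channel}' "
                f"(present: {sorted(self.traces)})"
            ) from None

    def discrete_samples(self, channel: str) -> list[tuple[float, float]]:
        """(time_s, value) pairs of one discrete channel, time-ordered."""
        sub = self.discrete[self.discrete["channel"] == channel]
        sub = sub.sort_values("time_s")
        return list(zip(sub["time_s"].astype(float),
                        sub["value"].astype(float)))


def write_session(session: RampSession, directory) -> list[Path]:
    """Write a session to ``directory``; returns the files written."""
    if not session.traces:
        raise ValueError("session has no continuous channels to write")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for name, tr in sorted(session.traces.items()):
        path = directory / f"{name}.csv"
        pd.DataFrame({"time_s": tr.times, "value": tr.values}).to_csv(
            path, index=False, float_format="%.17g")
        written.append(path)

    path = directory / "discrete.csv"
    session.discrete.to_csv(path, index=False, float_format="%.17g",
                            columns=["time_s", "value", "channel"])
    written.append(path)

    config = {
        "protocol": {
            "pre_rest_s": session.protocol.pre_rest_s,
            "p0_W": session.protocol.p0_W,
            "dp_W": session.protocol.dp_W,
            "step_s": session.protocol.step_s,
            "post_rest_s": session.protocol.post_rest_s,
        },
        "exhaustion_time_s": session.exhaustion_time_s,
        "body_mass_kg": session.body_mass_kg,
        "subject": session.subject,
        "channels": {name: session.traces[name].units
                     for name in sorted(session.traces)},
    }
    path = directory / "session.yaml"
    path.write_text(yaml.safe_dump(config, sort_keys=True))
    written.append(path)
    return written


def read_session(directory) -> RampSession:
    """Read a session previously written by :func:`write_session`."""
    directory = Path(directory)
    config = yaml.safe_load((directory / "session.yaml").read_text())
    protocol = RampProtocol(**config["protocol"])

    traces: dict[str, Trace] = {}
    for name, units in config["channels"].items():
        df = pd.read_csv(directory / f"{name}.csv",
                         float_precision="round_trip")
        traces[name] = Trace(df["time_s"].to_numpy(),
                             df["value"].to_numpy(),
                             channel=name, units=units)

    discrete = pd.read_csv(directory / "discrete.csv",
                           float_precision="round_trip")
    discrete["time_s"] = discrete["time_s"].astype(float)
    discrete["value"] = discrete["value"].astype(float)
    return RampSession(
        traces=traces,
        discrete=discrete,
        protocol=protocol,
        exhaustion_time_s=float(config["exhaustion_time_s"]),
        body_mass_kg=float(config["body_mass_kg"]),
        subject=str(config.get("subject", "anonymous")),
    )
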