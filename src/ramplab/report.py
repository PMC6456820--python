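"""PRE/POST change reporting.

After the 8-week training period the ramp test is repeated and every
extracted parameter is compared with its pre-training value as a
percentage change, 100 * (POST - PRE) / PRE. Undefined changes (PRE =
0, or a value missing on either side) propagate as missing, never as
zero. Report generation is deterministic: identical inputs produce
byte-identical JSON.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

__all__ = ["ParameterChange", "ChangeReport", "percent_change",
           "build_report"]


def percent_change(pre: float, post: float) -> float:
    """100 * (post - pre) / pre; NaN (undefined) when pre is 0."""
    if not math.isfinite(pre):
        raise ValueError("pre value must be finite")
    if pre == 0:
        return math.nan
    return 100.0 * (post - pre) / pre


@dataclass(frozen=True)
class ParameterChange:
    """PRE/POST pair and percent change of one parameter."""

    name: str
    pre: Optional[float]
    post: Optional[float]
    pct_change: Optional[float]     # None when undefined/missing
    group: str = ""                 # instrument grouping, e.g. "ramp"


@dataclass
class ChangeReport:
    """All parameter changes of one subject, PRE vs POST."""

    changes: list[ParameterChange]
    unmatched_pre: list[str]
    unmatched_post: list[str]
    subject: str = "anonymous"
    protocol_label: str = ""        # "CON" or "ECC"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "parameter": c.name, "group": c.group,
            "pre": c.pre, "post": c.post, "pct_change": c.pct_change,
        } for c in self.changes])

    def to_json(self) -> str:
        """Deterministic JSON (percent changes rounded to one decimal)."""
        payload = {
            "subject": self.subject,
            "protocol": self.protocol_label,
            "changes": [{
                "parameter": c.name,
                "group": c.group,
                "pre": c.pre,
                "post": c.post,
                "pct_change": (None if c.pct_change is None
                               else round(c.pct_change, 1)),
            } for c in self.changes],
            "unmatched_pre": self.unmatched_pre,
            "unmatched_post": self.unmatched_post,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _usable(value) -> bool:
    return value is not None and math.isfinite(value)


def build_report(pre: Mapping[str, Optional[float]],
                 post: Mapping[str, Optional[float]],
                 groups: Mapping[str, str] | None = None,
                 subject: str = "anonymous",
                 protocol_label: str = "") -> ChangeReport:
    """Percent change for every parameter present in both sets.

    ``pre`` and ``post`` map parameter names to values (``None`` for a
    measurement that failed). Parameters present on only one side are
    listed separately; a change is reported as missing when either
    value is unusable or PRE = 0. Ordering is deterministic
    (alphabetical).
    """
    shared = sorted(set(pre) & set(post))
    if not shared:
        raise ValueError("pre and post share no parameters")
    groups = groups or {}

    changes = []
    for name in shared:
        a, b = pre[name], post[name]
        if _usable(a) and _usable(b) and a != 0:
            pct = percent_change(a, b)
        else:
            pct = None
        changes.append(ParameterChange(
            name=name,
            pre=a if _usable(a) else None,
            post=b if _usable(b) else None,
            pct_change=pct,
            group=groups.get(name, ""),
        ))
    return ChangeReport(
        changes=changes,
        unmatched_pre=sorted(set(pre) - set(post)),
        unmatched_post=sorted(set(post) - set(pre)),
        subject=subject,
        protocol_label=protocol_label,
    )
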