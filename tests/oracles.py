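"""Independent brute-force reference implementations used by the tests.

These deliberately use naive loops rather than the vectorised code
paths they check.
"""

from __future__ import annotations

import numpy as np


def brute_force_window_peak(values: np.ndarray, fs: float,
                            window_s: float) -> float:
    """Max over all contiguous windows of round(window_s*fs) samples of
    the window mean, by explicit enumeration."""
    n = max(int(round(window_s * fs)), 1)
    best = -np.inf
    for i in range(len(values) - n + 1):
        m = sum(values[i:i + n]) / n
        if m > best:
            best = m
    return float(best)


def brute_force_smo2_min(times: np.ndarray, values: np.ndarray,
                         onset_rise_s: float = 30.0,
                         onset_min_rise: float = 2.0
                         ) -> tuple[float, float]:
    """Last-local-minimum-before-reoxygenation rule by explicit scan."""
    dt = times[1] - times[0]
    k = int(np.ceil(onset_rise_s / dt))

    # reoxygenation onset: first index at/after t=0 followed by k rising
    # steps that gain at least onset_min_rise overall
    onset_idx = None
    for i in range(len(values) - 1):
        if times[i] < 0:
            continue
        if i + k < len(values) and all(
                values[j + 1] > values[j] for j in range(i, i + k)) \
                and values[i + k] - values[i] >= onset_min_rise:
            onset_idx = i
            break
    end = onset_idx if onset_idx is not None else len(values) - 1

    start = next(i for i, t in enumerate(times) if t >= 0)
    last_min = None
    for i in range(max(start, 1), min(end, len(values) - 2) + 1):
        if values[i - 1] > values[i] <= values[i + 1]:
            last_min = i
    if last_min is None:
        seg = values[start:end + 1]
        last_min = start + int(np.argmin(seg))
    return float(values[last_min]), float(times[last_min])
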