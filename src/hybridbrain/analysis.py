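"""Seizure detection on region activity traces and propagation mapping.

A region is *recruited* into a seizure when its activity exceeds its own
baseline by a relative threshold (default 55%). The onset is the first
local maximum of the activity above that level; latencies of recruited
regions relative to the seizure source form the propagation map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SeizureCriteria",
    "PropagationMap",
    "baseline_activity",
    "detect_seizure",
    "propagation_map",
]


@dataclass(frozen=True)
class SeizureCriteria:
    """Detection rule: activity must rise ``rel_threshold`` above baseline.

    ``baseline_window`` (ms) is where the resting level is measured; it
    must precede the detection window and lie after the initial transient.
    ``smoothing`` is an optional moving-average width in ms (0 = none).
    """

    rel_threshold: float = 0.55
    baseline_window: tuple[float, float] = (3000.0, 5000.0)
    smoothing: float = 0.0
    transient: float = 2000.0

    def __post_init__(self) -> None:
        if self.rel_threshold <= 0:
            raise ValueError("rel_threshold must be > 0")
        t0, t1 = self.baseline_window
        if t1 <= t0:
            raise ValueError("baseline window must have positive length")


def _smooth(t: np.ndarray, y: np.ndarray, width: float) -> np.ndarray:
    if width <= 0:
        return y
    dt = t[1] - t[0]
    n = max(1, int(round(width / dt)))
    kernel = np.ones(n) / n
    return np.convolve(y, kernel, mode="same")


def baseline_activity(t: np.ndarray, nu: np.ndarray,
                      window: tuple[float, float],
                      transient: float = 0.0) -> float:
    """Mean activity over a window (the region's resting level)."""
    t = np.asarray(t)
    nu = np.asarray(nu)
    t0, t1 = window
    if t0 < transient:
        warnings.warn(
            f"baseline window starts at {t0} ms, inside the transient "
            f"({transient} ms); the estimate may be biased")
    m = (t >= t0) & (t <= t1)
    if not m.any():
        raise ValueError(f"baseline window {window} outside trace")
    return float(nu[m].mean())


def detect_seizure(
    t: np.ndarray,
    nu: np.ndarray,
    baseline: float,
    criteria: SeizureCriteria | None = None,
    search_from: float | None = None,
) -> float | None:
    """Onset time of a seizure, or None if the trace is never recruited.

    A seizure is present iff the activity reaches
    ``(1 + rel_threshold) * baseline``; its onset is the time of the first
    local maximum (three-point comparison) at or above that level after
    the first crossing. A trace that crosses the level but ends while
    still rising uses its last sample as the peak.

    The decision is invariant under rescaling trace and baseline together.
    """
    crit = criteria or SeizureCriteria()
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    t = np.asarray(t)
    nu = _smooth(t, np.asarray(nu, dtype=float), crit.smoothing)
    if search_from is not None:
        m = t >= search_from
        t, nu = t[m], nu[m]
    level = (1.0 + crit.rel_threshold) * baseline
    above = nu >= level
    if not above.any():
        return None
    i0 = int(np.argmax(above))
    # first local maximum at/after the crossing while above the level
    for i in range(max(i0, 1), len(nu) - 1):
        if nu[i] < level:
            continue
        if nu[i] >= nu[i - 1] and nu[i] > nu[i + 1]:
            return float(t[i])
    # rising at the end of the trace (or flat plateau): take the peak sample
    j = int(np.argmax(nu[i0:])) + i0
    return float(t[j])


@dataclass
class PropagationMap:
    """Seizure-arrival latencies relative to a source region.

    ``latencies[region]`` is onset(region) - onset(source) in ms, or None
    for regions never recruited. The source has latency exactly 0.
    """

    source: str
    latencies: dict

    def recruited(self) -> list[str]:
        return [r for r, l in self.latencies.items() if l is not None]

    def to_frame(self):
        import pandas as pd

        rows = [{"region": r,
                 "latency_ms": (np.nan if l is None else l),
                 "recruited": l is not None}
                for r, l in self.latencies.items()]
        return pd.DataFrame(rows)


def propagation_map(onsets: dict, source: str) -> PropagationMap:
    """Latency map from per-region onset times (None = not recruited)."""
    if source not in onsets or onsets[source] is None:
        raise ValueError(f"source region {source!r} has no seizure onset")
    t_src = onsets[source]
    lat = {}
    for region, onset in onsets.items():
        lat[region] = None if onset is None else float(onset - t_src)
    lat[source] = 0.0
    return PropagationMap(source=source, latencies=lat)
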