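"""Spiking-regime classification for potassium-bath neuron traces.

Assigns one of seven labels to a membrane-potential trace:

- ``RS``  resting state: no spikes, hyperpolarized.
- ``ST``  spike train: an initial volley of spikes, then silence.
- ``TS``  tonic spiking: regular spiking sustained to the end of the trace.
- ``BURSTING`` recurrent short spike clusters separated by quiescence.
- ``SLE`` seizure-like events: recurrent depolarized discharges lasting at
  least ~1 s, separated by quiescent periods of comparable length.
- ``SIA`` sustained ictal activity: uninterrupted fast spiking at a
  depolarized level, with no quiescent period.
- ``DB``  depolarization block: spiking ceases on a depolarized plateau.

The decision rules are heuristics over spike times and depolarized spans;
every threshold is exposed on :class:`ClassifierConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = ["Regime", "ClassifierConfig", "classify_regime", "depolarized_events"]


class Regime(str, Enum):
    RS = "RS"
    ST = "ST"
    TS = "TS"
    BURSTING = "BURSTING"
    SLE = "SLE"
    SIA = "SIA"
    DB = "DB"


class TraceTooShortError(ValueError):
    """Trace shorter than the minimum classifiable duration."""


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the regime decision tree (times in ms, voltages mV)."""

    spike_threshold: float = -25.0
    discard: float = 1000.0            # transient discarded before analysis
    min_duration: float = 10_000.0     # required total trace length
    rest_v: float = -50.0              # RS: tail mean below this
    plateau_v: float = -40.0           # DB: tail mean above this
    depol_v: float = -40.0             # level defining a depolarized span
    event_join: float = 300.0          # gaps shorter than this fuse spans
    st_fraction: float = 0.3           # ST: last spike within this fraction
    db_fraction: float = 0.5           # DB: no spike in trailing fraction
    tonic_cv: float = 0.3              # TS: ISI coefficient of variation
    tonic_gap_factor: float = 5.0      # TS: max ISI in units of median ISI
    tonic_v: float = -55.0             # TS vs SIA: mean V boundary
    sle_min_event: float = 1000.0      # SLE: event duration floor
    sle_min_gap: float = 1000.0        # SLE: quiescence floor


def detect_spike_times(t: np.ndarray, V: np.ndarray, threshold: float = -25.0) -> np.ndarray:
    """Upward threshold crossings; re-arm requires V back below threshold."""
    V = np.asarray(V)
    up = (V[1:] >= threshold) & (V[:-1] < threshold)
    return np.asarray(t)[1:][up]


def depolarized_events(
    t: np.ndarray, V: np.ndarray, level: float = -40.0, join: float = 300.0,
) -> list[tuple[float, float]]:
    """Contiguous spans with V above ``level``, fusing gaps shorter than ``join``.

    During fast spiking the potential dips below the level between spikes;
    the fuse width (longer than any tonic inter-spike interval) merges those
    dips so a discharge reads as one event.
    """
    idx = np.where(np.asarray(V) > level)[0]
    if len(idx) == 0:
        return []
    tt = np.asarray(t)[idx]
    brk = np.where(np.diff(tt) > join)[0]
    bounds = np.concatenate([[0], brk + 1, [len(tt)]])
    return [(float(tt[bounds[i]]), float(tt[bounds[i + 1] - 1]))
            for i in range(len(bounds) - 1)]


def classify_regime(
    t: np.ndarray,
    V: np.ndarray,
    config: ClassifierConfig | None = None,
) -> Regime:
    """Classify a single-cell membrane-potential trace.

    Raises :class:`TraceTooShortError` for traces shorter than
    ``config.min_duration`` (the slow ion dynamics need several seconds to
    express a regime).
    """
    cfg = config or ClassifierConfig()
    t = np.asarray(t, dtype=float)
    V = np.asarray(V, dtype=float)
    if t[-1] - t[0] < cfg.min_duration:
        raise TraceTooShortError(
            f"trace spans {t[-1] - t[0]:.0f} ms; "
            f"need >= {cfg.min_duration:.0f} ms to classify")
    keep = t >= t[0] + cfg.discard
    t, V = t[keep], V[keep]
    dur = t[-1] - t[0]
    spikes = detect_spike_times(t, V, cfg.spike_threshold)
    tail = V[t >= t[-1] - 0.1 * dur]
    v_tail = float(tail.mean())

    if len(spikes) == 0:
        if v_tail < cfg.rest_v:
            return Regime.RS
        if v_tail > cfg.plateau_v:
            return Regime.DB
        return Regime.RS  # intermediate quiet level: closest to rest

    last = spikes[-1] - t[0]
    if last < cfg.db_fraction * dur and v_tail > cfg.plateau_v:
        return Regime.DB
    if last < cfg.st_fraction * dur:
        return Regime.ST

    events = depolarized_events(t, V, cfg.depol_v, cfg.event_join)
    ev_dur = np.array([e - s for s, e in events])
    gaps = np.array([events[i + 1][0] - events[i][1]
                     for i in range(len(events) - 1)])
    isi = np.diff(spikes)
    if len(isi) >= 2:
        med_isi = float(np.median(isi))
        cv = float(isi.std() / isi.mean())
    else:
        med_isi, cv = np.inf, np.inf

    continuous = len(events) == 1 and ev_dur[0] > 0.9 * dur
    persistent = (
        len(spikes) > 10
        and np.max(isi) < cfg.tonic_gap_factor * med_isi
        and last > dur - cfg.tonic_gap_factor * med_isi
    )
    if continuous or (persistent and cv < cfg.tonic_cv):
        if cv < cfg.tonic_cv and float(V.mean()) < cfg.tonic_v:
            return Regime.TS
        return Regime.SIA
    if (len(events) >= 2 and len(gaps) > 0
            and np.median(ev_dur) >= cfg.sle_min_event
            and np.median(gaps) >= cfg.sle_min_gap):
        return Regime.SLE
    if len(events) >= 3:
        return Regime.BURSTING if np.median(ev_dur) < cfg.sle_min_event else Regime.SLE
    if persistent:
        return Regime.SIA
    return Regime.BURSTING
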