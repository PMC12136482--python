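"""Bidirectional translation between spikes and continuous region activity.

The detailed network speaks in discrete spike events; the whole-brain model
speaks in per-region mean activity (kHz per cell). Two spike->rate
converters are provided:

- plain binning: spike counts per bin, normalized by cell count and bin
  width, giving an instantaneous per-cell rate;
- a calcium-like filter: each cell carries a trace C_p that jumps by beta
  at every spike of that cell and decays exponentially with tau; the
  population mean <C_p> is a smooth activity measure (the normalization by
  N makes it invariant to the population size).

The inverse direction draws synthetic spike events whose count conforms to
a source region's activity (Poisson count, uniform timing over the epoch),
dispatched to every cell of the proxy population after the per-connection
delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import SpikeRaster

__all__ = [
    "CaFilterParams",
    "CouplingConfig",
    "ActivityTrace",
    "spikes_to_rate_binned",
    "ca_activity",
    "proxy_to_tvb",
    "rate_to_events",
]


@dataclass(frozen=True)
class CaFilterParams:
    """Calcium-like activity filter: decay tau (ms), per-spike jump beta."""

    tau_ca: float = 100.0
    beta_ca: float = 0.1

    def __post_init__(self) -> None:
        if self.tau_ca <= 0:
            raise ValueError("tau_ca must be > 0")


@dataclass(frozen=True)
class CouplingConfig:
    """Converter selection and scaling at the spikes<->activity boundary.

    ``G_A`` scales the proxy population activity into the gating slot of
    the coupling sum; ``rate_to_spike_gain`` converts region activity
    (kHz) to expected synthetic event counts per unit weight and ms;
    ``event_g`` is the synaptic conductance increment per synthetic event
    delivered to the proxy cells.
    """

    mode: str = "ca"                  # "binned" | "ca"
    bin_width: float = 1.0
    ca: CaFilterParams = CaFilterParams()
    G_A: float = 100.0
    rate_to_spike_gain: float = 1.0
    event_g: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.G_A <= 0:
            raise ValueError("G_A must be > 0")
        if self.mode not in ("binned", "ca"):
            raise ValueError(f"unknown converter mode {self.mode!r}")


@dataclass
class ActivityTrace:
    """Uniformly sampled population activity nu(t) in kHz per cell."""

    t: np.ndarray
    nu: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.nu = np.asarray(self.nu, dtype=float)
        if self.t.shape != self.nu.shape:
            raise ValueError("t and nu must have the same shape")

    def mean(self) -> float:
        return float(self.nu.mean())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t_ms": self.t, "nu_kHz": self.nu})


def spikes_to_rate_binned(
    raster: SpikeRaster,
    N: int,
    bin_width: float,
    span: tuple[float, float],
) -> ActivityTrace:
    """Per-cell firing rate from binned spike counts.

    nu(bin) = count / (N * bin_width), in kHz per cell for ms bins. The
    trace is sampled at bin centres.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    t0, t1 = span
    if t1 <= t0:
        raise ValueError(f"empty span {span}")
    edges = np.arange(t0, t1 + bin_width * 0.5, bin_width)
    if len(edges) < 2:
        raise ValueError("span shorter than one bin")
    counts, _ = np.histogram(raster.times, edges)
    nu = counts / (N * bin_width)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return ActivityTrace(t=centres, nu=nu)


def ca_activity(
    raster: SpikeRaster,
    N: int,
    params: CaFilterParams | None = None,
    dt: float = 1.0,
    span: tuple[float, float] = (0.0, 1000.0),
    C0: np.ndarray | None = None,
) -> ActivityTrace:
    """Population-mean calcium-like trace nu_P(t) = <C_p(t)>.

    Each cell's trace decays exponentially between its spikes and jumps by
    beta at each spike; initial condition C_p = 0 (or ``C0`` to continue a
    previous segment). Sampled every ``dt`` over ``span``; the sample at
    time t includes spikes at times <= t.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    p = params or CaFilterParams()
    t0, t1 = span
    if t1 <= t0:
        raise ValueError(f"empty span {span}")
    n_samp = int(round((t1 - t0) / dt))
    decay = np.exp(-dt / p.tau_ca)
    C = np.zeros(N) if C0 is None else np.asarray(C0, dtype=float).copy()
    if C.shape != (N,):
        raise ValueError("C0 has wrong shape")
    out = np.empty(n_samp)
    times = raster.times
    gids = raster.gids
    j = 0
    n_ev = len(times)
    # skip events before the span (they belong to earlier segments / C0)
    while j < n_ev and times[j] <= t0:
        j += 1
    for k in range(n_samp):
        t_hi = t0 + (k + 1) * dt
        C *= decay
        while j < n_ev and times[j] <= t_hi:
            # decay from sample edge to event time is folded into the
            # per-sample decay (events land on the integration grid in
            # practice; sub-sample placement is below the scheme's order)
            C[gids[j]] += p.beta_ca
            j += 1
        out[k] = C.mean()
    t = t0 + (np.arange(n_samp) + 1) * dt
    return ActivityTrace(t=t, nu=out)


def proxy_to_tvb(activity: ActivityTrace | np.ndarray, G_A: float = 100.0):
    """Scale proxy activity into the gating slot: substituted value = G_A * nu."""
    if isinstance(activity, ActivityTrace):
        return ActivityTrace(t=activity.t, nu=G_A * activity.nu)
    return G_A * np.asarray(activity, dtype=float)


def rate_to_events(
    nu_source: float,
    weight: float,
    epoch: tuple[float, float],
    gain: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Synthetic event times for one source region over one epoch.

    The event count is Poisson with mean
    ``gain * weight * nu_source * (t1 - t0)`` and timings are i.i.d.
    uniform over the epoch, returned sorted. Each event is subsequently
    dispatched to every proxy cell (broadcast) with the per-connection
    delay applied by the caller. The count law is a pluggable choice; this
    default treats the region activity as the intensity of a homogeneous
    Poisson process.
    """
    t0, t1 = epoch
    if t1 <= t0:
        raise ValueError(f"empty epoch {epoch}")
    if nu_source < 0:
        raise ValueError(f"negative source activity {nu_source}")
    lam = gain * weight * nu_source * (t1 - t0)
    n = rng.poisson(lam)
    times = rng.uniform(t0, t1, size=n)
    times.sort()
    return times
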