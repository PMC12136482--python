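"""Networks of potassium-bath neurons with exponential synapses.

A population of :mod:`hybridbrain.cell` neurons, split into a healthy
fraction ``f`` (low bath potassium, tonic spiking) and a pathological
remainder (elevated bath potassium, seizure-like events). Cells are wired
all-to-all (or not at all) with conductance-based single-exponential
synapses; spikes are threshold crossings of the membrane potential and are
delivered to targets after a transmission delay. The connectivity can be
switched on or off at scheduled times mid-run, which is how the
connect-after-independent-evolution experiment is expressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from ._kernels import integrate_network
from .cell import CellParams, CellState, IntegrationError, resting_state

__all__ = [
    "SynapseParams",
    "NetworkConfig",
    "SpikeRaster",
    "SpikingNetwork",
    "build_network",
    "detect_spikes",
    "simulate_network",
    "synchrony_index",
]


@dataclass(frozen=True)
class SynapseParams:
    """Conductance-based exponential synapse.

    ``weight`` is the dimensionless per-event weight w; the conductance
    increment per delivered spike is ``weight * g_unit`` (mS/cm^2), decaying
    with ``tau_syn`` toward zero. ``e_rev = 0`` makes synapses excitatory.
    """

    weight: float = 0.5
    tau_syn: float = 2.0
    e_rev: float = 0.0
    delay: float = 1.0
    g_unit: float = 0.1

    def __post_init__(self) -> None:
        if self.tau_syn <= 0:
            raise ValueError("tau_syn must be > 0")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")


@dataclass(frozen=True)
class NetworkConfig:
    """Population layout and wiring of a mixed healthy/pathological network."""

    N: int = 100
    f: float = 0.8
    K_bath_healthy: float = 9.5
    K_bath_path: float = 17.0
    synapse: SynapseParams = field(default_factory=SynapseParams)
    spike_threshold: float = -25.0
    connectivity: str = "all_to_all"   # "none" | "all_to_all"
    cell_params: CellParams = field(default_factory=CellParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.f <= 1.0):
            raise ValueError("f must lie in [0, 1]")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.connectivity not in ("none", "all_to_all"):
            raise ValueError(f"unknown connectivity {self.connectivity!r}")

    @property
    def n_healthy(self) -> int:
        """Round-half-up of f*N."""
        import math

        return int(math.floor(self.f * self.N + 0.5))


@dataclass
class SpikeRaster:
    """Time-sorted spike events (cell id, time in ms)."""

    times: np.ndarray
    gids: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.gids = np.asarray(self.gids, dtype=np.int64)
        if self.times.shape != self.gids.shape:
            raise ValueError("times and gids must have equal length")
        order = np.argsort(self.times, kind="stable")
        self.times = self.times[order]
        self.gids = self.gids[order]

    def __len__(self) -> int:
        return len(self.times)

    def for_cell(self, gid: int) -> np.ndarray:
        return self.times[self.gids == gid]

    def in_window(self, t0: float, t1: float) -> "SpikeRaster":
        m = (self.times >= t0) & (self.times < t1)
        return SpikeRaster(self.times[m], self.gids[m])

    @staticmethod
    def empty() -> "SpikeRaster":
        return SpikeRaster(np.empty(0), np.empty(0, dtype=np.int64))


class SpikingNetwork:
    """Population of potassium-bath neurons plus wiring.

    Construction assigns the first ``round_half_up(f*N)`` cells the healthy
    bath concentration and the rest the pathological one; the adjacency is
    either empty or all-to-all without self-connections.
    """

    def __init__(self, config: NetworkConfig):
        self.config = config
        N = config.N
        n_h = config.n_healthy
        self.healthy_mask = np.zeros(N, dtype=bool)
        self.healthy_mask[:n_h] = True
        baths = np.where(self.healthy_mask, config.K_bath_healthy,
                         config.K_bath_path)
        self.cell_params = [config.cell_params.with_bath(float(b)) for b in baths]
        self._params_matrix = np.stack([p.as_array() for p in self.cell_params])
        self.connected = config.connectivity == "all_to_all"
        # state initialised lazily by simulate_network
        self.states = np.stack([
            resting_state(p).as_array() for p in self.cell_params
        ])

    @property
    def N(self) -> int:
        return self.config.N

    def edges(self, connected: bool | None = None) -> list[tuple[int, int]]:
        on = self.connected if connected is None else connected
        if not on:
            return []
        N = self.N
        return [(i, j) for i in range(N) for j in range(N) if i != j]

    def adjacency_csr(self, connected: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """CSR (indptr, targets, per-target conductance increment)."""
        N = self.N
        syn = self.config.synapse
        w = syn.weight * syn.g_unit
        if not connected:
            indptr = np.zeros(N + 1, dtype=np.int64)
            return indptr, np.empty(0, dtype=np.int64), np.empty(0)
        targets = np.empty(N * (N - 1), dtype=np.int64)
        indptr = np.arange(0, N * (N - 1) + 1, N - 1, dtype=np.int64)
        for i in range(N):
            row = [j for j in range(N) if j != i]
            targets[indptr[i]:indptr[i + 1]] = row
        weights = np.full(N * (N - 1), w)
        return indptr, targets, weights


def build_network(config: NetworkConfig) -> SpikingNetwork:
    """Deterministically instantiate a mixed network from its config."""
    return SpikingNetwork(config)


def detect_spikes(t: np.ndarray, V: np.ndarray, threshold: float = -25.0) -> np.ndarray:
    """Spike times as upward threshold crossings on a uniform grid.

    One spike per crossing; the detector re-arms only after V falls back
    below the threshold.
    """
    from .classify import detect_spike_times

    return detect_spike_times(np.asarray(t), np.asarray(V), threshold)


@dataclass
class NetworkResult:
    t: np.ndarray
    V: np.ndarray              # (n_rec, N)
    raster: SpikeRaster
    config: NetworkConfig


def simulate_network(
    net: SpikingNetwork,
    T: float,
    dt: float = 0.0125,
    external_events: Sequence[tuple[float, int, float]] | None = None,
    switch_schedule: Sequence[tuple[float, bool]] | None = None,
    record_every: int = 1,
    v_bound: float = 500.0,
) -> NetworkResult:
    """Advance the network ``T`` ms and collect membrane traces and spikes.

    ``external_events`` is an iterable of ``(t_deliver_ms, target_gid,
    g_increment)`` with ``target_gid = -1`` broadcasting to every cell.
    Events beyond ``T`` are rejected with a warning. ``switch_schedule``
    lists ``(time_ms, connected_flag)`` pairs; the wiring changes take
    effect from the first step after the listed time.

    The per-cell update is the same kernel as :func:`simulate_cell`, so an
    unconnected, undriven network reproduces isolated-cell trajectories
    bit for bit.
    """
    import warnings

    cfg = net.config
    syn = cfg.synapse
    n_steps = int(round(T / dt))
    N = net.N

    ext = sorted(external_events or [], key=lambda e: e[0])
    kept = [(tt, g, w) for tt, g, w in ext if tt <= T]
    if len(kept) < len(ext):
        warnings.warn(f"dropped {len(ext) - len(kept)} external events beyond T={T}")
    ext_steps = np.array([int(round(tt / dt)) for tt, _, _ in kept], dtype=np.int64)
    ext_tgt = np.array([g for _, g, _ in kept], dtype=np.int64)
    ext_w = np.array([w for _, _, w in kept], dtype=np.float64)

    # segment boundaries at connectivity switches
    sched = sorted(switch_schedule or [], key=lambda s: s[0])
    for ts, _ in sched:
        if not (0.0 <= ts <= T):
            raise ValueError(f"switch time {ts} outside [0, {T}]")
    bounds = [0] + [int(round(ts / dt)) for ts, _ in sched] + [n_steps]
    flags = [net.connected] + [bool(on) for _, on in sched]

    states = net.states.copy()
    syn_g = np.zeros(N)
    n_rec = n_steps // record_every + 1
    v_rec = np.empty((n_rec, N))
    v_rec[0] = states[:, 0]
    pend_cap = max(16, N * 64)
    pend_t = np.zeros(pend_cap, dtype=np.int64)
    pend_tgt = np.zeros(pend_cap, dtype=np.int64)
    pend_w = np.zeros(pend_cap)
    n_pend = 0
    delay_steps = max(1, int(round(syn.delay / dt)))

    all_t = []
    all_g = []
    rec_offset = 0
    for seg in range(len(bounds) - 1):
        k0, k1 = bounds[seg], bounds[seg + 1]
        if k1 == k0:
            continue
        indptr, targets, weights = net.adjacency_csr(flags[seg])
        seg_rec = (k1 - k0) // record_every + 1
        v_seg = np.empty((seg_rec, N))
        v_seg[0] = states[:, 0]
        spk_t, spk_g, n_pend, t_fail = integrate_network(
            states, net._params_matrix, dt, k1 - k0, k0, syn_g,
            indptr, targets, weights, syn.tau_syn, syn.e_rev, delay_steps,
            ext_steps, ext_tgt, ext_w, cfg.spike_threshold,
            v_seg, record_every, pend_t, pend_tgt, pend_w, n_pend, v_bound)
        if t_fail >= 0:
            raise IntegrationError(f"network integration diverged at t = {t_fail:.6g} ms")
        all_t.append(spk_t)
        all_g.append(spk_g)
        v_rec[rec_offset + 1: rec_offset + seg_rec] = v_seg[1:]
        rec_offset += seg_rec - 1

    raster = SpikeRaster(np.concatenate(all_t) if all_t else np.empty(0),
                         np.concatenate(all_g) if all_g else np.empty(0, np.int64))
    t = np.arange(n_rec) * (dt * record_every)
    return NetworkResult(t=t, V=v_rec, raster=raster, config=cfg)


def synchrony_index(raster: SpikeRaster, N: int, t0: float, t1: float,
                    bin_width: float = 20.0) -> float:
    """Population synchrony in [0, 1] from binned spike counts.

    The variance-to-mean construction of Golomb & Rinzel: the ratio of the
    variance of the population-mean binned rate to the mean single-cell
    variance. 1 = perfectly locked population, ~0 = asynchronous.
    """
    window = raster.in_window(t0, t1)
    edges = np.arange(t0, t1 + bin_width, bin_width)
    if len(edges) < 3:
        raise ValueError("window too short for the requested bin width")
    counts = np.zeros((N, len(edges) - 1))
    for gid in range(N):
        counts[gid], _ = np.histogram(window.times[window.gids == gid], edges)
    pop = counts.mean(axis=0)
    var_pop = pop.var()
    var_cells = counts.var(axis=1).mean()
    if var_cells == 0:
        return 0.0
    return float(var_pop / var_cells)
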