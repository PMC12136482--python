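"""Epoch-based co-simulation of a spiking proxy inside the whole-brain model.

One (or more) connectome regions are replaced by proxy nodes: detailed
spiking networks whose population activity stands in for the region's
gating variable. Both scales advance in lockstep over *epochs* of length
tau_min (the smallest inter-region delay): because any influence between
regions takes at least tau_min to arrive, each side can integrate a full
epoch independently, and data is exchanged only at epoch boundaries.

Per epoch k:

1. synthetic events for the proxy cells are generated from every region I
   with an inbound weight c_PI > 0, using the previous epoch's mean rate
   nu_I; each event is broadcast to all proxy cells after the
   per-connection delay tau_PI >= tau_min (so it lands in epoch k+1 or
   later);
2. the spiking network advances one epoch, consuming events scheduled for
   this window;
3. its spikes are converted to a smooth activity trace (calcium-like
   filter by default) and written, scaled by G_A, into the proxy row of
   the mass model's delay history;
4. the mass model advances one epoch; other regions read the substituted
   proxy activity through their delayed couplings.

Single-process orchestration; the exchange contract (what crosses the
boundary, and when) is what a distributed backend would have to honour.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from ._kernels import integrate_network
from .cell import IntegrationError
from .coupling import ActivityTrace, CaFilterParams, CouplingConfig, \
    rate_to_events, spikes_to_rate_binned
from .massmodel import Connectome, MassModel, RWWParams, RegionTraces, firing_rate
from .network import NetworkConfig, SpikeRaster, SpikingNetwork, build_network

__all__ = ["CosimConfig", "EpochPlan", "validate_schedule", "CosimResult", "run_cosim"]


@dataclass(frozen=True)
class CosimConfig:
    """Full configuration of a co-simulation run."""

    proxy_region: str
    T: float = 20_000.0
    epoch: float | None = None          # None -> tau_min
    dt_micro: float = 0.0125
    dt_macro: float = 0.1
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    rww: RWWParams = field(default_factory=RWWParams)
    initial_S: float = 0.001
    seed: int = 0


@dataclass
class EpochPlan:
    """Resolved exchange schedule."""

    epoch: float
    n_epochs: int
    macro_steps_per_epoch: int
    micro_steps_per_epoch: int
    tau_min: float


def _divides(small: float, big: float, tol: float = 1e-9) -> bool:
    r = big / small
    return abs(r - round(r)) < tol and round(r) >= 1


def validate_schedule(connectome: Connectome, config: CosimConfig) -> EpochPlan:
    """Resolve and validate the epoch plan.

    The exchange interval must not exceed tau_min (delayed-exchange
    correctness), and both time steps must divide it evenly.
    """
    tau_min = connectome.tau_min(config.dt_macro)
    epoch = config.epoch if config.epoch is not None else tau_min
    if epoch > tau_min + 1e-12:
        raise ValueError(
            f"epoch {epoch} ms exceeds tau_min {tau_min} ms; events could "
            "arrive inside the epoch they were generated in")
    if not _divides(config.dt_macro, epoch):
        raise ValueError(f"dt_macro={config.dt_macro} does not divide epoch={epoch}")
    if not _divides(config.dt_micro, epoch):
        raise ValueError(f"dt_micro={config.dt_micro} does not divide epoch={epoch}")
    n_epochs = int(config.T / epoch + 1e-9)
    if n_epochs < 1:
        raise ValueError(f"T={config.T} is shorter than one epoch ({epoch})")
    if abs(config.T - n_epochs * epoch) > 1e-9:
        warnings.warn(
            f"T={config.T} is not a multiple of the epoch {epoch}; "
            f"simulating {n_epochs * epoch:.6g} ms ({n_epochs} epochs)")
    return EpochPlan(
        epoch=epoch,
        n_epochs=n_epochs,
        macro_steps_per_epoch=int(round(epoch / config.dt_macro)),
        micro_steps_per_epoch=int(round(epoch / config.dt_micro)),
        tau_min=tau_min,
    )


@dataclass
class CosimResult:
    regions: RegionTraces            # S and nu per region (proxy row = dummy)
    proxy_activity: ActivityTrace    # nu_P(t), kHz per cell
    proxy_V: np.ndarray              # (n_rec, N) membrane potentials
    proxy_V_t: np.ndarray
    raster: SpikeRaster
    exchange_log: list
    plan: EpochPlan
    config: CosimConfig


def run_cosim(config: CosimConfig, connectome: Connectome,
              record_every_micro: int = 8) -> CosimResult:
    """Run the two-scale loop; deterministic given config seeds.

    Event generation uses one independent RNG stream per (source region,
    epoch), so results do not depend on evaluation order.
    """
    plan = validate_schedule(connectome, config)
    P = connectome.index_of(config.proxy_region)
    n_reg = connectome.n_regions
    cc = config.coupling

    # --- macro side -------------------------------------------------------
    model = MassModel(connectome, config.rww, config.dt_macro,
                      config.initial_S, proxy_regions=[config.proxy_region])
    # substituted values enter through the history, not through rww_rhs
    model.proxy_mask[:] = False
    m_steps = plan.macro_steps_per_epoch

    # --- micro side -------------------------------------------------------
    net = build_network(config.network)
    N = net.N
    dt = config.dt_micro
    u_steps = plan.micro_steps_per_epoch
    states = net.states.copy()
    syn_g = np.zeros(N)
    indptr, targets, weights_csr = net.adjacency_csr(net.connected)
    pend_cap = max(64, N * 64)
    pend_t = np.zeros(pend_cap, dtype=np.int64)
    pend_tgt = np.zeros(pend_cap, dtype=np.int64)
    pend_w = np.zeros(pend_cap)
    n_pend = 0
    delay_steps = max(1, int(round(config.network.synapse.delay / dt)))

    # inbound weights and delays into the proxy
    w_in = connectome.weights[P].copy()
    w_in[P] = 0.0
    delays_in = connectome.delays(config.dt_macro)[P]
    sources = np.where(w_in > 0)[0]

    # per-epoch state
    nu_prev = np.zeros(n_reg)        # epoch-mean H(x_I) of the previous epoch
    C_state = np.zeros(N)            # calcium filter state
    ca_decay = math.exp(-config.dt_macro / cc.ca.tau_ca)
    pending_ext: list[tuple[float, float]] = []   # (delivery time, conductance)

    n_rec_micro = (plan.n_epochs * u_steps) // record_every_micro + 1
    proxy_V = np.empty((n_rec_micro, N))
    proxy_V[0] = states[:, 0]
    rec_off = 0

    S_all = np.empty((plan.n_epochs * m_steps, n_reg))
    x_all = np.empty((plan.n_epochs * m_steps, n_reg))
    nu_P_all = np.empty(plan.n_epochs * m_steps)
    rasters_t, rasters_g = [], []
    exchange_log = []

    for k in range(plan.n_epochs):
        t0 = k * plan.epoch
        t1 = t0 + plan.epoch

        # (1) synthetic events from every inbound region, using nu of the
        # previous epoch; delivery after the per-connection delay
        emitted = {}
        if k > 0:
            for I in sources:
                rng = np.random.default_rng([config.seed, int(I), k])
                ev = rate_to_events(float(nu_prev[I]), float(w_in[I]),
                                    (t0, t1), cc.rate_to_spike_gain, rng)
                if len(ev):
                    emitted[int(I)] = len(ev)
                for te in ev:
                    pending_ext.append((te + delays_in[I], cc.event_g))
        # events due in the current epoch
        due = [(te, g) for te, g in pending_ext if t0 < te <= t1]
        pending_ext = [(te, g) for te, g in pending_ext if te > t1]
        due.sort()
        ext_steps = np.array([int(round(te / dt)) for te, _ in due], dtype=np.int64)
        ext_tgt = np.full(len(due), -1, dtype=np.int64)     # broadcast
        ext_w = np.array([g for _, g in due], dtype=np.float64)

        # (2) advance the spiking network one epoch
        seg_rec = u_steps // record_every_micro + 1
        v_seg = np.empty((seg_rec, N))
        v_seg[0] = states[:, 0]
        spk_t, spk_g, n_pend, t_fail = integrate_network(
            states, net._params_matrix, dt, u_steps, k * u_steps, syn_g,
            indptr, targets, weights_csr,
            config.network.synapse.tau_syn, config.network.synapse.e_rev,
            delay_steps, ext_steps, ext_tgt, ext_w,
            config.network.spike_threshold, v_seg, record_every_micro,
            pend_t, pend_tgt, pend_w, n_pend, 500.0)
        if t_fail >= 0:
            raise IntegrationError(
                f"proxy network diverged at t = {t_fail:.6g} ms (epoch {k})")
        rasters_t.append(spk_t)
        rasters_g.append(spk_g)
        proxy_V[rec_off + 1: rec_off + seg_rec] = v_seg[1:]
        rec_off += seg_rec - 1

        # (3) spikes -> smooth activity on the macro grid
        if cc.mode == "ca":
            nu_seg = np.empty(m_steps)
            j = 0
            for s in range(m_steps):
                t_hi = t0 + (s + 1) * config.dt_macro
                C_state *= ca_decay
                while j < len(spk_t) and spk_t[j] <= t_hi:
                    C_state[spk_g[j]] += cc.ca.beta_ca
                    j += 1
                nu_seg[s] = C_state.mean()
        else:
            tr = spikes_to_rate_binned(SpikeRaster(spk_t, spk_g), N,
                                       config.dt_macro, (t0, t1))
            nu_seg = tr.nu

        # (4) advance the mass model one epoch, then substitute the proxy
        # activity into its history so delayed reads in later epochs see it
        S_seg, x_seg = model.advance(m_steps)
        sub = cc.G_A * nu_seg
        st = model.state
        for s in range(m_steps):
            row = (st.head + (m_steps - 1 - s)) % st.depth
            st.history[row, P] = sub[s]
        sl = slice(k * m_steps, (k + 1) * m_steps)
        S_all[sl] = S_seg
        x_all[sl] = x_seg
        nu_P_all[sl] = nu_seg
        nu_prev = firing_rate(x_seg, config.rww).mean(axis=0)

        exchange_log.append({
            "epoch": k,
            "t0": t0,
            "t1": t1,
            "events_emitted": emitted,
            "events_delivered": len(due),
            "spikes": len(spk_t),
        })

    t_macro = (np.arange(plan.n_epochs * m_steps) + 1) * config.dt_macro
    nu = firing_rate(x_all, config.rww)
    regions = RegionTraces(t=t_macro, S=S_all, nu=nu,
                           labels=list(connectome.labels))
    raster = SpikeRaster(np.concatenate(rasters_t) if rasters_t else np.empty(0),
                         np.concatenate(rasters_g) if rasters_g else np.empty(0, np.int64))
    t_micro = np.arange(n_rec_micro) * (dt * record_every_micro)
    return CosimResult(
        regions=regions,
        proxy_activity=ActivityTrace(t=t_macro, nu=nu_P_all),
        proxy_V=proxy_V[:rec_off + 1],
        proxy_V_t=t_micro[:rec_off + 1],
        raster=raster,
        exchange_log=exchange_log,
        plan=plan,
        config=config,
    )
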