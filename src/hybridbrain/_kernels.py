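"""Numba inner loops for the cell and network integrators.

The single-cell update ``_step`` is shared verbatim by the isolated-cell
and network integrators so that an unconnected network reproduces isolated
cells bit-for-bit (same floating-point operation sequence).

Parameter vector layout (see CellParams.as_array):
0 cm, 1 g0_K, 2 g0_Na, 3 g0_Cl, 4 gl_K, 5 gl_Na, 6 rho, 7 gamma_ion,
8 epsilon, 9 beta_vol, 10 K_bath, 11 C_nernst, 12 tau_n, 13 pump_K_stoich,
14 K0_i, 15 Na0_i, 16 Cl0_i, 17 K0_o, 18 Na0_o, 19 Cl0_o
"""

import math

import numpy as np
from numba import njit

__all__ = ["integrate_cell", "integrate_network"]


@njit(cache=True, inline="always")
def _step(V, n, dKi, Kg, p, dt, i_syn):
    """One fixed step: explicit Euler on V/dKi/Kg, exponential update on n."""
    K_i = p[14] + dKi
    Na_i = p[15] - dKi
    K_o = p[17] - p[9] * dKi + Kg
    Na_o = p[18] + p[9] * dKi
    E_K = p[11] * math.log(K_o / K_i)
    E_Na = p[11] * math.log(Na_o / Na_i)
    E_Cl = p[11] * math.log(p[16] / p[19])
    m = 1.0 / (1.0 + math.exp(-(24.0 + V) / 12.0))
    h = 1.1 - 1.0 / (1.0 + math.exp(3.2 - 8.0 * n))
    i_K = (p[1] * n + p[4]) * (V - E_K)
    i_Na = (p[2] * m * h + p[5]) * (V - E_Na)
    i_Cl = p[3] * (V - E_Cl)
    i_pump = p[6] / ((1.0 + math.exp((21.0 - Na_i) / 2.0))
                     * (1.0 + math.exp(5.5 - K_o)))
    V_new = V + dt * (-(i_K + i_Na + i_Cl + i_pump - i_syn) / p[0])
    n_inf = 1.0 / (1.0 + math.exp(-(19.0 + V) / 18.0))
    n_new = n_inf + (n - n_inf) * math.exp(-dt / p[12])
    dKi_new = dKi + dt * (-p[7] * (i_K - p[13] * i_pump))
    Kg_new = Kg + dt * (p[8] * (p[10] - K_o))
    return V_new, n_new, dKi_new, Kg_new


@njit(cache=True)
def integrate_cell(state0, p, dt, n_steps, record_every, drive, v_bound):
    """Integrate one cell; returns (records, t_fail). t_fail < 0 on success."""
    n_rec = n_steps // record_every + 1
    out = np.empty((n_rec, 4))
    V, n, dKi, Kg = state0[0], state0[1], state0[2], state0[3]
    out[0, 0] = V
    out[0, 1] = n
    out[0, 2] = dKi
    out[0, 3] = Kg
    j = 1
    has_drive = drive.shape[0] > 0
    for k in range(1, n_steps + 1):
        i_syn = drive[k - 1] if has_drive else 0.0
        V, n, dKi, Kg = _step(V, n, dKi, Kg, p, dt, i_syn)
        if not math.isfinite(V) or abs(V) > v_bound:
            return out[:j], k * dt
        if k % record_every == 0:
            out[j, 0] = V
            out[j, 1] = n
            out[j, 2] = dKi
            out[j, 3] = Kg
            j += 1
    return out[:j], -1.0


@njit(cache=True)
def integrate_network(
    states,        # (N, 4) initial state per cell
    params,        # (N, 20) parameter vector per cell
    dt,
    n_steps,
    t0_step,       # global step index at segment start (for event times)
    syn_g,         # (N,) synaptic conductance state (mS/cm^2), mutated
    adj_indptr,    # CSR over source cells -> target list
    adj_targets,
    adj_weights,   # conductance increment per spike at each target
    syn_tau,
    syn_erev,
    delay_steps,   # internal network delay in steps
    ext_t_steps,   # external events: delivery step (sorted), absolute
    ext_target,    # external events: target cell (-1 = broadcast to all)
    ext_weight,    # conductance increment
    spike_thr,
    v_record,      # (n_rec, N) output buffer, row 0 pre-filled ok
    record_every,
    pend_t,        # pending internal deliveries: absolute step
    pend_target,
    pend_w,
    n_pend,        # number of valid pending entries
    v_bound,
):
    """Advance a network segment; returns (spikes, new_n_pend, t_fail).

    Event-driven exponential synapses: per-cell conductance decays as
    exp(-dt/tau) each step; a spike at cell i schedules, after the internal
    delay, a conductance increment at each of its targets. External events
    (from the co-simulation boundary) arrive pre-scheduled in ext_* arrays.
    The pending ring (pend_*) carries deliveries across segment boundaries.
    """
    N = states.shape[0]
    decay = math.exp(-dt / syn_tau)
    above = np.zeros(N, dtype=np.bool_)
    for i in range(N):
        above[i] = states[i, 0] >= spike_thr
    max_spikes = min(4_000_000, N * n_steps + 16)
    spk_t = np.empty(max_spikes)
    spk_gid = np.empty(max_spikes, dtype=np.int64)
    n_spk = 0
    ext_i = 0
    # skip external events already delivered
    while ext_i < ext_t_steps.shape[0] and ext_t_steps[ext_i] < t0_step:
        ext_i += 1
    j = 1
    for k in range(1, n_steps + 1):
        gstep = t0_step + k
        # deliver pending internal events scheduled for this step
        w = 0
        for e in range(n_pend):
            if pend_t[e] == gstep:
                syn_g[pend_target[e]] += pend_w[e]
            else:
                pend_t[w] = pend_t[e]
                pend_target[w] = pend_target[e]
                pend_w[w] = pend_w[e]
                w += 1
        n_pend = w
        # deliver external events due this step
        while ext_i < ext_t_steps.shape[0] and ext_t_steps[ext_i] == gstep:
            tgt = ext_target[ext_i]
            if tgt < 0:
                for i in range(N):
                    syn_g[i] += ext_weight[ext_i]
            else:
                syn_g[tgt] += ext_weight[ext_i]
            ext_i += 1
        # advance every cell with its synaptic current, then decay conductance
        for i in range(N):
            V = states[i, 0]
            i_syn = syn_g[i] * (syn_erev - V)
            V2, n2, dKi2, Kg2 = _step(V, states[i, 1], states[i, 2],
                                      states[i, 3], params[i], dt, i_syn)
            if not math.isfinite(V2) or abs(V2) > v_bound:
                return spk_t[:n_spk], spk_gid[:n_spk], n_pend, gstep * dt
            states[i, 0] = V2
            states[i, 1] = n2
            states[i, 2] = dKi2
            states[i, 3] = Kg2
            # threshold crossing with re-arm below threshold
            if V2 >= spike_thr and not above[i]:
                if n_spk < max_spikes:
                    spk_t[n_spk] = gstep * dt
                    spk_gid[n_spk] = i
                    n_spk += 1
                # schedule internal deliveries
                for a in range(adj_indptr[i], adj_indptr[i + 1]):
                    if n_pend < pend_t.shape[0]:
                        pend_t[n_pend] = gstep + delay_steps
                        pend_target[n_pend] = adj_targets[a]
                        pend_w[n_pend] = adj_weights[a]
                        n_pend += 1
            above[i] = V2 >= spike_thr
            syn_g[i] *= decay
        if k % record_every == 0:
            for i in range(N):
                v_record[j, i] = states[i, 0]
            j += 1
    return spk_t[:n_spk], spk_gid[:n_spk], n_pend, -1.0
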