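# hybridbrain

Multi-scale co-simulation of seizure onset and whole-brain propagation:
a biophysical potassium-bath neuron model and spiking networks of such
neurons (micro scale), a reduced Wong-Wang mean-field model on a delayed
structural connectome (macro scale), and the bidirectional spike ↔ rate
coupling that embeds the first inside the second. It is written for
computational neuroscientists who want to study how epileptiform activity
generated by a small population of biophysically detailed cells spreads
through a whole-brain network, without coupling two full simulation
platforms together.

## The models

**Single cell.** A spherical single-compartment neuron immersed in a bath
of fixed potassium concentration `K_bath`. The fast subsystem is a reduced
Hodgkin-Huxley pair (V, n),

```
cm dV/dt = -(i_K + i_Na + i_Cl + i_pump - i_syn)
 i_X     = g_X (V - E_X),    E_X = C ln(X_o / X_i)
 g_K     = g0_K n + gl_K,    g_Na = g0_Na m_inf(V) h(n) + gl_Na,   g_Cl = g0_Cl
 i_pump  = rho / ((1 + exp((21 - Na_i)/2)) (1 + exp(5.5 - K_o)))
 dn/dt   = (n_inf(V) - n) / tau_n
```

with sodium activation instantaneous (`m = m_inf(V)`) and inactivation
slaved to the potassium gate (`h = h(n)`). The slow subsystem moves ion
concentrations: the intracellular potassium deviation and the bath buffer

```
 d(dKi)/dt = -gamma (i_K - i_pump)
 dKg/dt    = epsilon (K_bath - K_o)
```

with the bookkeeping `K_i = K0_i + dKi`, `Na_i = Na0_i - dKi`,
`K_o = K0_o - beta dKi + Kg`, `Na_o = Na0_o + beta dKi` and static
chloride. Raising `K_bath` drives the cell through resting state (RS),
spike train (ST), tonic spiking (TS), bursting, seizure-like events (SLE),
sustained ictal activity (SIA) and depolarization block (DB).

**Whole brain.** Each region I carries the mean NMDA gating S_I of the
reduced Wong-Wang model,

```
 dS_I/dt = -S_I/tau_s + (1 - S_I) gamma H(x_I)
 H(x)    = (a x - b) / (1 - exp(-d (a x - b)))
 x_I     = w J_N S_I + G J_N sum_K c_IK S_K(t - tau_IK) + I_0
```

on a connectome of weights `c_IK` and conduction delays
`tau_IK = length_IK / speed`.

**Coupling.** A chosen region becomes a *proxy node*: a spiking network
whose population activity (a calcium-like filtered trace,
`dC_p/dt = -C_p/tau + beta sum_spikes delta(t - t_spike)`,
`nu_P = <C_p>`) replaces the region's gating in every delayed coupling
sum, scaled by a factor `G_A`. In the other direction, each region with an
inbound connection to the proxy emits synthetic spike events (Poisson
count matched to its rate, uniform timing) to all proxy cells. Both sides
advance in lockstep over *epochs* no longer than the smallest inter-region
delay, so no exchange is ever needed mid-epoch.

## A worked example

```
python examples/single_cell_regimes.py
```

prints (10-s simulation per row, spike threshold -25 mV):

```
 K_bath (mM)     regime   spikes  mean V (mV)
         4.0         RS        5        -75.1
         7.5         TS       70        -68.9
         9.5         TS      125        -65.3
        12.5   BURSTING      247        -64.1
        17.0        SLE      532        -54.0
        17.5        SIA      705        -39.1
        22.5         DB        3        -30.5
```

Reading the table: at 4 mM the cell fires only a handful of start-up
spikes and rests near -75 mV; at 9.5 mM it spikes tonically (12.5 Hz); at
12.5 mM the spikes come in clusters; at 17 mM the clusters become
seizure-like discharges lasting over a second; at 17.5 mM the ictal firing
never pauses; and at 22.5 mM the membrane locks at a depolarized plateau
(~-30 mV) where spiking is impossible — depolarization block.

The other examples show network entrainment by a pathological minority
(`examples/network_entrainment.py`), the resting state of the whole-brain
model (`examples/whole_brain_resting_state.py`) and seizure propagation
from an embedded proxy (`examples/seizure_propagation.py`).

A small CLI wraps the same entry points:
`hybridbrain cell-sweep`, `hybridbrain net-run`, `hybridbrain cosim-run`,
`hybridbrain analyze`.

## Layout

- `src/hybridbrain/cell.py` — potassium-bath neuron (types, currents, integrator)
- `src/hybridbrain/classify.py` — regime classifier
- `src/hybridbrain/network.py` — spiking networks, exponential synapses, synchrony
- `src/hybridbrain/massmodel.py` — reduced Wong-Wang model with delay buffer
- `src/hybridbrain/coupling.py` — spike↔rate converters, proxy scaling, event generation
- `src/hybridbrain/cosim.py` — epoch-based two-scale orchestration
- `src/hybridbrain/analysis.py` — seizure detection and propagation maps
- `src/hybridbrain/io.py` — connectome/raster formats, synthetic connectome, manifests
- `docs/methods.md` — model assumptions, parameter provenance, numerical choices
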