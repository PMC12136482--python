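# Methods

This note records the modeling assumptions, parameter provenance, and
numerical choices behind `hybridbrain`, at the level of detail a user needs
to judge what results mean and where they stop applying.

## Single-cell model

The cell is a single-compartment neuron whose membrane carries gated K, Na
and Cl currents plus an Na/K pump, and whose intra-/extracellular ion
concentrations evolve slowly under those currents and under buffering of
extracellular potassium by an external bath. The state is (V, n, ΔK_i, K_g):
membrane potential, the delayed-rectifier activation, the intracellular
potassium deviation from baseline, and the bath-exchange variable. Two
standard reductions make the fast subsystem two-dimensional: sodium
activation is instantaneous, m = m∞(V) = 1/(1+exp(−(V+24)/12)), and sodium
inactivation is slaved to the potassium gate, h(n) = 1.1 − 1/(1+exp(3.2−8n))
(the familiar h ≈ const − n collapse). Potassium activation relaxes to
n∞(V) = 1/(1+exp(−(V+19)/18)) with time constant τ_n.

Concentration bookkeeping is algebraic, not integrated: K_i = K0_i + ΔK_i,
Na_i = Na0_i − ΔK_i (one-for-one electroneutral exchange),
K_o = K0_o − β·ΔK_i + K_g and Na_o = Na0_o + β·ΔK_i with β the ICS/ECS
volume ratio; chloride is static. The conservation identities
Na_i + ΔK_i = Na0_i and K_i − ΔK_i = K0_i therefore hold exactly at all
times. Reversal potentials use E_X = C ln(X_o/X_i) with C = 26.64 mV
(RT/F near body temperature); chloride, being an anion, swaps the ratio.

The pump current is
i_pump = ρ / ((1+exp((21−Na_i)/2))(1+exp(5.5−K_o))), and the potassium
balance uses the single-pump form dΔK_i/dt = −γ(i_K − i_pump). The classic
3Na:2K stoichiometry (a factor 2 on the pump term) is available as
`pump_K_stoich`; calibration favored the single-pump form.

### Parameter provenance and calibration

Units package-wide: ms, mV, mM, µA/cm², mS/cm², µF/cm². The numeric
constants of this model family are not uniquely fixed by its published
descriptions, so the default `CellParams` set was *calibrated*: the free
constants (conductances, ρ, γ, ε, β, τ_n, baseline concentrations) were
searched numerically until the regime ladder under increasing K_bath
appears at the canonical bath values, simulated and classified entirely
through the package's own pipeline (10-s runs, dt = 0.0125 ms):

| K_bath (mM) | 4.0 | 9.5 | 12.5 | 17.0 | 17.5 | 20–22 | 22.5 |
|---|---|---|---|---|---|---|---|
| regime | RS | TS | bursting | SLE | SIA | SIA | DB |

Depolarization block first appears at exactly 22.5 mM on a 0.5 mM grid
over 15–25 mM — and in particular not at 20 mM. The labels are unchanged
at dt = 0.025 and dt = 0.00625 ms, so the placement is a property of the
equations, not of the step size.

One regime resisted calibration: at K_bath = 7.5 mM the default set fires
sustained ~7 Hz tonic spikes rather than a transient spike train (ST)
followed by silence. Moving the firing onset above 7.5 mM (mainly via the
maximal sodium conductance) consistently destroyed the depolarization-block
boundary at 22.5 mM, across extensive single-knob and random multi-knob
searches. We kept the set that places the other six regimes correctly and
document the ST deviation rather than trade it against the block boundary.
τ_n = 8 ms (longer than the 4 ms typical for this family) is part of that
outcome: shorter gate time constants leave the 9.5 mM attractor a
mixed-mode oscillation instead of regular tonic spiking.

### Integrator

Fixed-step splitting: explicit Euler on V, ΔK_i and K_g, with the gating
variable updated by its exact exponential relaxation toward n∞(V) over the
step (the linear-in-n subsystem is solved, not stepped — a first-order
splitting in the same spirit as solving gating implicitly). Default
dt = 0.0125 ms; halving dt changes a settled resting trajectory's V(1 s)
by well under 0.1 mV (asserted in the test suite). Divergence (|V| >
500 mV or non-finite state) aborts with the offending time. Initial
conditions default to the fast-subsystem rest at baseline concentrations
(bisection on dV/dt = 0 with n = n∞); for parameter sets with no true rest
the scan point of smallest |dV/dt| is used.

### Regime classifier

The classifier works on spike times (upward −25 mV crossings, re-armed
below threshold) and *depolarized events* — spans with V above −40 mV,
fused across gaps shorter than 300 ms so the inter-spike dips inside a
discharge do not split it. After discarding the first second: no spikes
means RS (hyperpolarized tail) or DB (tail above −40 mV); spikes confined
to the first 30% mean ST; spiking that persists to the end with ISI
CV < 0.3 and no gap above 5 median ISIs means TS (mean V below −55 mV) or
SIA; recurrent depolarized events of at least 1 s separated by at least
1 s of quiescence mean SLE; shorter recurrent clusters mean bursting;
persistent irregular firing with no second-long pause means SIA. All
thresholds live on `ClassifierConfig`. Traces shorter than 10 s are
refused: the slow ion dynamics need several seconds to express a regime.

## Spiking network

Networks are homogeneous populations of the cell above, split into a
healthy fraction f (round-half-up of f·N cells) at one bath value and a
pathological remainder at another. Connectivity is all-to-all without
self-connections, or absent. Synapses are conductance-based single
exponentials: each delivered spike increments the target's synaptic
conductance by w·g_unit and the conductance decays with τ_syn toward zero;
the synaptic current is g_syn(E_rev − V). Defaults: w = 0.5, τ_syn = 2 ms,
E_rev = 0 mV (excitatory), transmission delay 1 ms, g_unit = 0.1 mS/cm²
per unit weight. Whether these synapses should be current- or
conductance-based is not fixed by the problem statement; conductance-based
was chosen as the biophysically safer default (currents saturate as V
approaches E_rev). g_unit was calibrated so that the mixed 80/20 network,
connected after 5 s of free evolution, audibly locks to the pathological
rhythm: population synchrony (variance of the population-mean binned rate
over mean single-cell variance) rises from 0.51 to 0.88.

The per-cell update inside the network integrator is the same compiled
kernel as the isolated-cell integrator, executed in the same order, so an
unconnected or zero-weight network reproduces isolated-cell trajectories
bit for bit — the decoupling contract is exact, not approximate.

## Whole-brain model

The reduced Wong-Wang model with the standard constants a = 0.27 nC⁻¹,
b = 0.108 kHz, d = 154 ms, γ = 0.641, τ_s = 100 ms, J_N = 0.2609 nA,
I_0 = 0.33 nA, ω = 1, G = 0.096. The transfer H(x) handles its removable
singularity at a·x = b explicitly (quadratic expansion of the
denominator), making it continuous, positive and strictly increasing;
H(b/a) = 1/d ≈ 6.494 Hz exactly.

Integration is explicit Euler at dt = 0.1 ms with S clamped to [0, 1]
after each step (protection against Euler overshoot at the boundaries).
Delays are tract length over conduction speed (default 3 mm/ms), rounded
to the nearest step; zero-length connected pairs get a delay of one step,
because the exchange scheme requires every inter-region delay positive.
The delay history is a ring buffer whose state is explicit, so advancing
the model in chunks of any size is bitwise identical to one monolithic
run — that property is what makes epoch-based co-simulation exact rather
than approximately correct. dt must divide the smallest inter-region delay
τ_min; the schedule validator enforces this. Initial S defaults to 0.001
uniformly; runs discard a transient (2 s by convention in the analysis
defaults) before measuring baselines. Activity ν = H(x) is kept in kHz
internally; outputs label units explicitly.

## Coupling layer

Spikes → rate: either plain binning (count / (N·Δt), a per-cell rate in
kHz) or the calcium-like filter dC_p/dt = −C_p/τ + β Σ δ(t−t_spike,p) with
τ = 100 ms and β = 0.1 per spike, population activity ν_P = ⟨C_p⟩. The
division by N (the population mean) is what makes both converters
invariant under duplicating the population; a per-spike β of 0.1 with the
explicit mean realizes the intended "β normalized by cell count" without
the normalization cancelling. In the stationary regime the two converters'
time averages differ by exactly the factor β·τ (asserted in tests). The
co-simulation uses the calcium filter by default: with a 100-cell proxy,
binned rates on millisecond bins are too ragged a drive for the smooth
mean-field dynamics.

Rate → spikes: for each region I with an inbound weight c_PI > 0 to the
proxy, the epoch's event count is Poisson with mean
gain·c_PI·ν_I·epoch_length, timings i.i.d. uniform over the epoch, and
every event is broadcast to all proxy cells with the per-connection delay
τ_PI applied. The count law is a declared customization point — nothing in
the mean-rate contract fixes the microscopic statistics — and homogeneous
Poisson is the minimal-assumption default. Event weights are constant;
the connectome weight modulates counts, not amplitudes.

Proxy → whole brain: the substituted value is G_A·ν_P(t) with G_A = 100,
written into the proxy's row of the delay history so that every other
region reads it through its own delayed coupling, in place of S_P. The
substitution targets the gating slot (the coupling sum consumes gating
values), not the transfer function's output.

## Co-simulation

Single-process orchestration preserving the exchange contract of a
distributed design: per epoch (default τ_min), (1) generate inbound events
for the proxy from the previous epoch's mean rates, (2) advance the
spiking network one epoch, (3) convert its spikes to the smooth activity
trace and write it (scaled by G_A) into the mass model's history, (4)
advance the mass model one epoch. Because every inter-region delay is at
least τ_min, events and activity generated in epoch k can first influence
the other side in epoch k+1 — causality is structural, not scheduled.
Event generation draws from an independent RNG stream keyed by (seed,
source region, epoch index), so results are independent of evaluation
order and a longer run reproduces a shorter run's exchange history as its
prefix. Runs are bitwise reproducible given the config seeds, and a proxy
with zero in/out weights reproduces both standalone simulations bit for
bit.

The rate used for event generation is the epoch-mean of H(x_I) over the
previous epoch. With epochs of a few milliseconds this loses nothing
measurable against per-step tables while keeping the exchange record one
number per region per epoch.

## Synthetic connectome

The generator emulates the gross statistics of an atlas-derived mouse
connectome: 98 regions in two mirror-symmetric hemispheres (identical
intra-hemispheric blocks, symmetric inter-hemispheric block), log-normal
weights (median e^−2 ≈ 0.135), uniform tract lengths on 3–60 mm quantized
to 0.3 mm so all conduction delays land exactly on the 0.1 ms macro grid,
connection density 0.3. It does **not** emulate: the heavy-tailed degree
distribution and spatial embedding of real connectomes, distance-dependent
weight decay, or the specific hippocampal circuitry of the real mouse
brain. Tests passing on this surrogate therefore demonstrate the
mechanics of embedding, exchange, detection and latency mapping — not
anatomical fidelity of any particular propagation pattern.

## Seizure detection and propagation

Per region, the baseline is the mean activity over a configurable window
after the transient; a seizure is detected iff the activity reaches
(1 + 0.55)·baseline, with the onset at the first local maximum (three-point
rule) at or above that level after the crossing; a trace still rising at
its end uses its last sample. Detection is invariant under rescaling trace
and baseline together, and raising the threshold can only shrink the
recruited set. Region-specific sensitivity comes from the per-region
baselines; the relative threshold is shared, with per-region overrides
possible. No smoothing is applied by default; an optional moving average
is exposed (with noisy traces the first-local-maximum rule otherwise
latches onto wiggles on the rising flank). Latencies are onsets minus the
source onset; non-recruited regions are reported as absent rather than
given a fictitious latency.

## Problem sizes used in the shipped tests and examples

Single-cell sweeps run 10 s per bath value. The entrainment experiment
uses 100 cells for 10 s; the whole-brain surrogate uses a 100-cell proxy
in the 98-region synthetic connectome for 20 s, where the proxy's
seizure-like discharges recruit ~25 of 97 regions under the 55% criterion
and push every connected region visibly off the proxy-free steady state.
These sizes were chosen as the smallest that express each phenomenon
clearly; all scale linearly in duration and cell count.

## Known limitations

- The cell parameter set is a calibrated reconstruction, not a published
  table; the spike-train regime at 7.5 mM is the one rung of the ladder it
  does not reproduce (see above).
- The whole-brain model is deterministic (no noise term), so "resting
  state" means a fixed point, not stationary fluctuations.
- Synaptic physiology is minimal: one excitatory exponential synapse type,
  no inhibitory subpopulation, no plasticity.
- The rate→spike direction is one of many defensible inverses of the
  spike→rate map; conclusions that depend on the microscopic statistics of
  inbound events should treat it as a modeling choice.
- Morphology is absent by construction: cells are points, and nothing here
  addresses dendritic computation.
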