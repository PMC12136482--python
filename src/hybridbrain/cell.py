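"""Single-compartment potassium-bath neuron.

A Hodgkin-Huxley-type point neuron immersed in a potassium bath. Ion
concentrations inside (ICS) and outside (ECS) the membrane evolve under
voltage-gated K/Na/Cl currents, an active Na/K pump, and diffusive buffering
of extracellular potassium by the bath. The bath concentration ``K_bath``
is the single control parameter: sweeping it moves the cell through resting
state (RS), spike train (ST), tonic spiking (TS), bursting, seizure-like
events (SLE), sustained ictal activity (SIA) and depolarization block (DB).

State variables: membrane potential ``V`` (mV), the delayed-rectifier
gating variable ``n``, the intracellular potassium deviation ``dKi`` (mM)
and the bath-buffer variable ``Kg`` (mM). Sodium activation is taken as
instantaneous, ``m = m_inf(V)``; sodium inactivation is slaved to the
potassium gate through ``h = h(n)``, so the fast subsystem is
two-dimensional.

Units package-wide: ms, mV, mM, uA/cm^2, mS/cm^2, uF/cm^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from enum import Enum
from typing import Callable

import numpy as np

from ._kernels import integrate_cell

__all__ = [
    "CellParams",
    "CellState",
    "CellTrace",
    "IntegrationError",
    "nernst_potential",
    "gating_n_inf",
    "gating_m_inf",
    "gating_h_of_n",
    "derived_concentrations",
    "ionic_currents",
    "cell_rhs",
    "resting_state",
    "simulate_cell",
]


class IntegrationError(RuntimeError):
    """Raised when a trajectory diverges (|V| above bound, or NaN)."""


@dataclass(frozen=True)
class CellParams:
    """Biophysical constants of the potassium-bath neuron.

    The default set reproduces the canonical regime ladder under increasing
    ``K_bath`` (see :func:`hybridbrain.classify.classify_regime`); the
    calibration is documented in ``docs/methods.md``.

    Attributes
    ----------
    cm : membrane capacitance (uF/cm^2).
    g0_K, g0_Na, g0_Cl : maximal gated conductances (mS/cm^2).
    gl_K, gl_Na : leak conductances (mS/cm^2).
    rho : Na/K pump strength (uA/cm^2).
    gamma_ion : current-density to molar-flux conversion (mM cm^2 / uC).
    epsilon : bath <-> ECS potassium exchange rate (1/ms).
    beta_vol : ICS/ECS volume ratio (dimensionless).
    K_bath : bath potassium concentration (mM); the control parameter.
    C_nernst : Nernst prefactor RT/F (mV).
    tau_n : time constant of the potassium gate (ms).
    pump_K_stoich : potassium-flux weight of the pump current in the
        intracellular K balance (2 for the 3Na:2K stoichiometry).
    K0_i .. Cl0_o : baseline ICS/ECS concentrations (mM).
    """

    cm: float = 1.0
    g0_K: float = 23.93
    g0_Na: float = 40.0
    g0_Cl: float = 5.75
    gl_K: float = 0.045
    gl_Na: float = 0.02
    rho: float = 59.25
    gamma_ion: float = 5.1e-5
    epsilon: float = 0.035
    beta_vol: float = 3.441
    K_bath: float = 4.8
    C_nernst: float = 26.64
    tau_n: float = 8.0
    pump_K_stoich: float = 1.0
    K0_i: float = 130.0
    Na0_i: float = 18.47
    Cl0_i: float = 4.86
    K0_o: float = 4.8
    Na0_o: float = 138.0
    Cl0_o: float = 112.0

    def __post_init__(self) -> None:
        for name in ("g0_K", "g0_Na", "g0_Cl", "gl_K", "gl_Na"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")
        for name in ("K0_i", "Na0_i", "Cl0_i", "K0_o", "Na0_o", "Cl0_o",
                     "K_bath"):
            if getattr(self, name) <= 0:
                raise ValueError(f"concentration {name} must be > 0")
        if self.tau_n <= 0:
            raise ValueError("tau_n must be > 0")
        if self.cm <= 0:
            raise ValueError("cm must be > 0")

    def with_bath(self, K_bath: float) -> "CellParams":
        """Copy of the parameter set at a different bath concentration."""
        return replace(self, K_bath=K_bath)

    def as_array(self) -> np.ndarray:
        """Pack into the flat float64 vector used by the numba kernels."""
        return np.array([
            self.cm, self.g0_K, self.g0_Na, self.g0_Cl, self.gl_K,
            self.gl_Na, self.rho, self.gamma_ion, self.epsilon,
            self.beta_vol, self.K_bath, self.C_nernst, self.tau_n,
            self.pump_K_stoich, self.K0_i, self.Na0_i, self.Cl0_i,
            self.K0_o, self.Na0_o, self.Cl0_o,
        ], dtype=np.float64)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CellState:
    """Dynamical state (V, n, dKi, Kg)."""

    V: float
    n: float
    dKi: float = 0.0
    Kg: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.n, self.dKi, self.Kg], dtype=np.float64)

    def validate(self, params: CellParams) -> None:
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite cell state: {self}")
        conc = derived_concentrations(self, params)
        bad = [k for k, v in conc.items() if v <= 0]
        if bad:
            raise ValueError(f"non-positive derived concentrations {bad}: {self}")


@dataclass
class CellTrace:
    """Fixed-step trajectory of a single cell."""

    t: np.ndarray
    V: np.ndarray
    n: np.ndarray
    dKi: np.ndarray
    Kg: np.ndarray
    params: CellParams | None = None

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "t_ms": self.t, "V_mV": self.V, "n": self.n,
            "dKi_mM": self.dKi, "Kg_mM": self.Kg,
        })


def nernst_potential(X_o: float, X_i: float, C_nernst: float = 26.64) -> float:
    """Reversal potential ``C * ln(X_o / X_i)`` for a monovalent cation.

    For anions (chloride) call with the concentrations swapped, which is
    equivalent to the sign flip of the valence.
    """
    if X_o <= 0 or X_i <= 0:
        raise ValueError(f"concentrations must be > 0 (got X_o={X_o}, X_i={X_i})")
    return C_nernst * math.log(X_o / X_i)


def gating_n_inf(V: float) -> float:
    """Steady-state activation of the delayed-rectifier potassium gate."""
    return 1.0 / (1.0 + math.exp(-(19.0 + V) / 18.0))


def gating_m_inf(V: float) -> float:
    """Instantaneous sodium activation."""
    return 1.0 / (1.0 + math.exp(-(24.0 + V) / 12.0))


def gating_h_of_n(n: float) -> float:
    """Sodium inactivation slaved to the potassium gate, h = h(n).

    Rinzel-style reduction exploiting the approximate conservation
    h + n ~ const along trajectories.
    """
    return 1.1 - 1.0 / (1.0 + math.exp(3.2 - 8.0 * n))


def derived_concentrations(state: CellState, params: CellParams) -> dict:
    """Ion concentrations implied by (dKi, Kg) via the bookkeeping rules.

    Intracellular K and Na exchange one-for-one (electroneutral drift), the
    ECS mirrors the ICS scaled by the volume ratio, and chloride is static:

    ``K_i = K0_i + dKi``, ``Na_i = Na0_i - dKi``, ``Cl_i = Cl0_i``,
    ``K_o = K0_o - beta*dKi + Kg``, ``Na_o = Na0_o + beta*dKi``,
    ``Cl_o = Cl0_o``.
    """
    p = params
    return {
        "K_i": p.K0_i + state.dKi,
        "Na_i": p.Na0_i - state.dKi,
        "Cl_i": p.Cl0_i,
        "K_o": p.K0_o - p.beta_vol * state.dKi + state.Kg,
        "Na_o": p.Na0_o + p.beta_vol * state.dKi,
        "Cl_o": p.Cl0_o,
    }


def ionic_currents(state: CellState, params: CellParams) -> tuple[float, float, float, float]:
    """Current densities (i_K, i_Na, i_Cl, i_pump) in uA/cm^2.

    ``i_X = g_X (V - E_X)`` with ``g_K = g0_K n + gl_K``,
    ``g_Na = g0_Na m_inf(V) h(n) + gl_Na`` and ``g_Cl = g0_Cl``; the pump
    current is the product of sodium and potassium sigmoids scaled by rho.
    """
    vals = state.as_array()
    if not np.all(np.isfinite(vals)):
        raise ValueError(f"NaN/Inf in cell state: {state}")
    p = params
    c = derived_concentrations(state, params)
    if min(c.values()) <= 0:
        raise ValueError(f"non-positive concentration in {c}")
    E_K = nernst_potential(c["K_o"], c["K_i"], p.C_nernst)
    E_Na = nernst_potential(c["Na_o"], c["Na_i"], p.C_nernst)
    # chloride carries valence -1: swap in/out
    E_Cl = nernst_potential(c["Cl_i"], c["Cl_o"], p.C_nernst)
    V, n = state.V, state.n
    m = gating_m_inf(V)
    h = gating_h_of_n(n)
    i_K = (p.g0_K * n + p.gl_K) * (V - E_K)
    i_Na = (p.g0_Na * m * h + p.gl_Na) * (V - E_Na)
    i_Cl = p.g0_Cl * (V - E_Cl)
    i_pump = p.rho / ((1.0 + math.exp((21.0 - c["Na_i"]) / 2.0))
                      * (1.0 + math.exp(5.5 - c["K_o"])))
    return i_K, i_Na, i_Cl, i_pump


def cell_rhs(state: CellState, params: CellParams, i_syn: float = 0.0) -> np.ndarray:
    """Time derivative (dV, dn, d(dKi), dKg) of the full state.

    ``i_syn`` is an inward synaptic current density (uA/cm^2); positive
    values depolarize.
    """
    p = params
    i_K, i_Na, i_Cl, i_pump = ionic_currents(state, params)
    dV = -(i_K + i_Na + i_Cl + i_pump - i_syn) / p.cm
    dn = (gating_n_inf(state.V) - state.n) / p.tau_n
    ddKi = -p.gamma_ion * (i_K - p.pump_K_stoich * i_pump)
    K_o = p.K0_o - p.beta_vol * state.dKi + state.Kg
    dKg = p.epsilon * (p.K_bath - K_o)
    return np.array([dV, dn, ddKi, dKg])


def resting_state(params: CellParams, V_lo: float = -95.0, V_hi: float = -30.0) -> CellState:
    """Initial condition: fast-subsystem rest at baseline concentrations.

    Solves ``dV/dt = 0`` with ``n = n_inf(V)`` and dKi = Kg = 0 by bisection
    on the first sign change from the hyperpolarized end. When the fast
    subsystem has no equilibrium in the bracket (spontaneously active
    parameter sets), the scan point with the smallest |dV/dt| is returned
    instead: integration then starts from the slowest point of the cycle.
    """

    def f(V: float) -> float:
        st = CellState(V=V, n=gating_n_inf(V))
        i_K, i_Na, i_Cl, i_pump = ionic_currents(st, params)
        return -(i_K + i_Na + i_Cl + i_pump)

    grid = np.linspace(V_lo, V_hi, 261)
    vals = np.array([f(v) for v in grid])
    V_root = None
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            V_root = float(grid[i])
            break
        if vals[i] * vals[i + 1] < 0:
            a, b = float(grid[i]), float(grid[i + 1])
            for _ in range(80):
                mid = 0.5 * (a + b)
                if f(a) * f(mid) <= 0:
                    b = mid
                else:
                    a = mid
            V_root = 0.5 * (a + b)
            break
    if V_root is None:
        V_root = float(grid[int(np.argmin(np.abs(vals)))])
    return CellState(V=V_root, n=gating_n_inf(V_root))


def simulate_cell(
    params: CellParams,
    T: float,
    dt: float = 0.0125,
    i_syn_fn: Callable[[float], float] | None = None,
    initial: CellState | None = None,
    record_every: int = 1,
    v_bound: float = 500.0,
) -> CellTrace:
    """Integrate the cell for ``T`` ms with fixed step ``dt``.

    Explicit Euler on (V, dKi, Kg) with an exact exponential update of the
    gating variable n (the stiff, linear-in-n part of the splitting).
    Deterministic given inputs. Raises :class:`IntegrationError` naming the
    time of failure if |V| exceeds ``v_bound`` or turns non-finite.

    ``i_syn_fn(t)`` supplies an optional time-dependent synaptic drive
    sampled at every step; ``record_every`` thins the stored trajectory.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if T < dt:
        raise ValueError("T must be >= dt")
    if initial is None:
        initial = resting_state(params)
    initial.validate(params)
    n_steps = int(round(T / dt))
    if i_syn_fn is None:
        drive = np.zeros(0)  # kernel treats empty as zero drive
    else:
        drive = np.array([i_syn_fn(k * dt) for k in range(n_steps)], dtype=np.float64)
    out, t_fail = integrate_cell(initial.as_array(), params.as_array(), dt,
                                 n_steps, int(record_every), drive, v_bound)
    if t_fail >= 0:
        raise IntegrationError(f"integration diverged at t = {t_fail:.6g} ms")
    t = np.arange(out.shape[0]) * (dt * record_every)
    return CellTrace(t=t, V=out[:, 0], n=out[:, 1], dKi=out[:, 2],
                     Kg=out[:, 3], params=params)
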