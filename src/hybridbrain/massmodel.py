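"""Reduced Wong-Wang whole-brain model on a delayed connectome.

Each brain region I carries one state variable, the mean NMDA synaptic
gating S_I in [0, 1]:

    dS_I/dt = -S_I / tau_s + (1 - S_I) * gamma * H(x_I)
    H(x)    = (a x - b) / (1 - exp(-d (a x - b)))
    x_I     = omega J_N S_I + G J_N sum_K c_IK S_K(t - tau_IK) + I_0

with the sigmoidal-like transfer H mapping total input current (nA) to a
population firing rate (kHz). Region-to-region interaction is delayed by
tract length over conduction speed. Time is in ms throughout.

A proxy feed can replace selected regions' gating values inside other
regions' coupling sums: that is the hook by which a detailed spiking
network is embedded into the whole-brain model (see
:mod:`hybridbrain.cosim`).
"""

from __future__ import annotations

import math
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "Connectome",
    "RWWParams",
    "MassModelState",
    "firing_rate",
    "rww_rhs",
    "MassModel",
    "simulate_tvb",
    "isolated_fixed_point",
]


@dataclass
class Connectome:
    """Region labels, coupling weights, tract lengths and derived delays.

    ``weights[i, k]`` is the strength c_IK of the connection from region k
    into region i; ``tract_lengths`` are in mm, ``speed`` in mm/ms. Delays
    are ``tract_lengths / speed``; entries on the diagonal and zero-weight
    entries are ignored when computing ``tau_min``. Zero delays on connected
    off-diagonal pairs are replaced by ``zero_delay_value`` (the exchange
    scheme requires every inter-region delay to be positive).
    """

    labels: list[str]
    weights: np.ndarray
    tract_lengths: np.ndarray
    speed: float = 3.0
    zero_delay_value: float | None = None   # defaults to dt at simulation time

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.tract_lengths = np.asarray(self.tract_lengths, dtype=float)
        n = len(self.labels)
        if self.weights.shape != (n, n):
            raise ValueError(
                f"weights shape {self.weights.shape} does not match {n} labels")
        if self.tract_lengths.shape != (n, n):
            raise ValueError(
                f"tract_lengths shape {self.tract_lengths.shape} "
                f"does not match {n} labels")
        if np.any(self.weights < 0):
            raise ValueError("connectome weights must be non-negative")
        if np.any(self.tract_lengths < 0):
            raise ValueError("tract lengths must be non-negative")
        if self.speed <= 0:
            raise ValueError("conduction speed must be > 0")

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def delays(self, dt: float | None = None) -> np.ndarray:
        """Delay matrix in ms with zero entries of connected pairs replaced.

        The replacement value is ``zero_delay_value`` if set, else ``dt``.
        """
        d = self.tract_lengths / self.speed
        fill = self.zero_delay_value
        if fill is None:
            if dt is None:
                raise ValueError("need dt to substitute zero delays")
            fill = dt
        off = ~np.eye(self.n_regions, dtype=bool)
        connected = (self.weights > 0) & off
        d = d.copy()
        d[connected & (d <= 0)] = fill
        return d

    def tau_min(self, dt: float | None = None) -> float:
        """Smallest delay over connected inter-region pairs."""
        d = self.delays(dt)
        connected = (self.weights > 0) & ~np.eye(self.n_regions, dtype=bool)
        if not connected.any():
            raise ValueError("connectome has no inter-region connections")
        return float(d[connected].min())

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"region {label!r} not in connectome") from None


@dataclass(frozen=True)
class RWWParams:
    """Reduced Wong-Wang constants (defaults as used for resting state).

    a (nC^-1), b (kHz) and d (ms) shape the input-rate transfer H;
    gamma_kin and tau_s set the gating kinetics; J_N (nA) the synaptic
    coupling; I_0 (nA) the baseline drive; omega the local recurrence and
    G the global coupling scale.
    """

    a: float = 0.270
    b: float = 0.108
    d: float = 154.0
    gamma_kin: float = 0.641
    tau_s: float = 100.0
    J_N: float = 0.2609
    I_0: float = 0.33
    omega: float = 1.0
    G: float = 0.096

    def __post_init__(self) -> None:
        for name in ("a", "b", "d", "gamma_kin", "tau_s", "J_N"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class MassModelState:
    """Per-region gating with its delay history ring buffer.

    ``history[j]`` holds S at time ``t - j*dt`` for j in [0, depth);
    row 0 is the current value.
    """

    S: np.ndarray
    history: np.ndarray
    head: int = 0

    @property
    def depth(self) -> int:
        return self.history.shape[0]


def firing_rate(x: np.ndarray | float, params: RWWParams | None = None):
    """Input-output transfer H(x) in kHz for input current x in nA.

    The removable singularity at a*x = b is handled by the quadratic
    expansion of the denominator; H is continuous, positive and strictly
    increasing.
    """
    p = params or RWWParams()
    x_arr = np.asarray(x, dtype=float)
    scalar = x_arr.ndim == 0
    u = np.atleast_1d(p.a * x_arr - p.b)
    du = p.d * u
    out = np.empty_like(u)
    small = np.abs(du) < 1e-6
    # u / (1 - exp(-d u)) -> 1/d * 1 / (1 - du/2 + du^2/6) near du = 0
    out[small] = (1.0 / p.d) / (1.0 - du[small] / 2.0 + du[small] ** 2 / 6.0)
    us = u[~small]
    out[~small] = us / (1.0 - np.exp(-p.d * us))
    if scalar:
        return float(out[0])
    return out


def rww_rhs(
    S: np.ndarray,
    S_delayed: np.ndarray,
    params: RWWParams,
    weights: np.ndarray,
    proxy_mask: np.ndarray | None = None,
    proxy_values: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """dS/dt and the per-region input x.

    ``S_delayed[i, k]`` must hold S_K(t - tau_IK). When ``proxy_mask`` is
    given, the marked columns of the coupling sum use ``proxy_values``
    (the substituted activity of proxy regions) in place of the regions'
    own delayed gating.
    """
    S_eff = S_delayed
    if proxy_mask is not None and proxy_mask.any():
        if proxy_values is None:
            raise ValueError("proxy_mask given without proxy_values")
        S_eff = S_delayed.copy()
        S_eff[:, proxy_mask] = proxy_values[proxy_mask]
    coupling = (weights * S_eff).sum(axis=1)
    x = params.omega * params.J_N * S + params.G * params.J_N * coupling + params.I_0
    H = firing_rate(x, params)
    dS = -S / params.tau_s + (1.0 - S) * params.gamma_kin * H
    return dS, x


class MassModel:
    """Fixed-step delayed integrator for the reduced Wong-Wang network.

    Explicit Euler with gating clamped to [0, 1] after each step (guards
    against Euler overshoot at the boundaries). Delays are rounded to the
    nearest step. The integrator state is explicit, so a run may be
    advanced in arbitrary chunks; chunking does not change the arithmetic
    (monolithic and epoch-chunked runs agree bitwise).
    """

    def __init__(
        self,
        connectome: Connectome,
        params: RWWParams | None = None,
        dt: float = 0.1,
        initial_S: float | np.ndarray = 0.001,
        proxy_regions: list[str] | None = None,
    ):
        self.connectome = connectome
        self.params = params or RWWParams()
        self.dt = float(dt)
        n = connectome.n_regions
        delays = connectome.delays(self.dt)
        self.delay_steps = np.rint(delays / self.dt).astype(np.int64)
        self.delay_steps[self.delay_steps < 1] = 1
        np.fill_diagonal(self.delay_steps, 0)
        depth = int(self.delay_steps.max()) + 1
        S0 = np.full(n, float(initial_S)) if np.isscalar(initial_S) \
            else np.asarray(initial_S, dtype=float).copy()
        if S0.shape != (n,):
            raise ValueError("initial_S has wrong shape")
        hist = np.tile(S0, (depth, 1))
        self.state = MassModelState(S=S0.copy(), history=hist)
        self.t_step = 0
        self.proxy_mask = np.zeros(n, dtype=bool)
        if proxy_regions:
            for lab in proxy_regions:
                self.proxy_mask[connectome.index_of(lab)] = True
        self._rows = np.arange(n)

    def _delayed_matrix(self) -> np.ndarray:
        """S_delayed[i, k] = S_k(t - tau_ik) from the ring buffer."""
        st = self.state
        idx = (st.head + self.delay_steps) % st.depth
        return st.history[idx, np.arange(st.history.shape[1])[None, :]]

    def advance(
        self,
        n_steps: int,
        proxy_values_fn=None,
        record: bool = True,
    ) -> tuple[np.ndarray, np.ndarray] | None:
        """Advance ``n_steps``; optionally return (S, x) at every step.

        ``proxy_values_fn(step_index)`` supplies the substituted activity
        of proxy regions (full-length vector; only proxy entries are read)
        at each local step.
        """
        n = self.connectome.n_regions
        S_out = np.empty((n_steps, n)) if record else None
        x_out = np.empty((n_steps, n)) if record else None
        st = self.state
        use_proxy = self.proxy_mask.any()
        for k in range(n_steps):
            pv = proxy_values_fn(k) if (use_proxy and proxy_values_fn is not None) else None
            dS, x = rww_rhs(st.S, self._delayed_matrix(), self.params,
                            self.connectome.weights,
                            self.proxy_mask if use_proxy else None, pv)
            S_new = st.S + self.dt * dS
            np.clip(S_new, 0.0, 1.0, out=S_new)
            st.head = (st.head - 1) % st.depth
            st.history[st.head] = S_new
            st.S = S_new
            self.t_step += 1
            if record:
                S_out[k] = S_new
                x_out[k] = x
        if record:
            return S_out, x_out
        return None


@dataclass
class RegionTraces:
    """Per-region activity: gating S and firing rate nu = H(x) (kHz)."""

    t: np.ndarray
    S: np.ndarray
    nu: np.ndarray
    labels: list[str]

    def region(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        i = self.labels.index(label)
        return self.S[:, i], self.nu[:, i]

    def to_frame(self):
        import pandas as pd

        n_t, n_r = self.S.shape
        return pd.DataFrame({
            "t_ms": np.repeat(self.t, n_r),
            "region": np.tile(self.labels, n_t),
            "S": self.S.ravel(),
            "nu_kHz": self.nu.ravel(),
        })


def simulate_tvb(
    connectome: Connectome,
    params: RWWParams | None = None,
    T: float = 10_000.0,
    dt: float = 0.1,
    initial_S: float | np.ndarray = 0.001,
    proxy_feed=None,
    proxy_regions: list[str] | None = None,
    record_every: int = 1,
    check_divisibility: bool = True,
) -> RegionTraces:
    """Whole-brain resting-state run returning S_I(t) and nu_I(t) = H(x_I).

    Requires ``dt`` to divide the smallest inter-region delay exactly (the
    epoch-exchange correctness condition); pass
    ``check_divisibility=False`` only for standalone exploratory runs.
    """
    params = params or RWWParams()
    tau_min = connectome.tau_min(dt)
    if check_divisibility:
        ratio = tau_min / dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"dt={dt} must evenly divide tau_min={tau_min}")
    model = MassModel(connectome, params, dt, initial_S,
                      proxy_regions=proxy_regions)
    n_steps = int(round(T / dt))
    S, x = model.advance(n_steps, proxy_values_fn=proxy_feed)
    nu = firing_rate(x, params)
    sl = slice(record_every - 1, None, record_every)
    t = (np.arange(n_steps) + 1)[sl] * dt
    return RegionTraces(t=t, S=S[sl], nu=nu[sl], labels=list(connectome.labels))


def isolated_fixed_point(params: RWWParams | None = None) -> float:
    """Fixed point S* of a single uncoupled region, by bracketed root search.

    Solves S/tau_s = (1 - S) gamma H(omega J_N S + I_0) on [0, 1].
    """
    from scipy.optimize import brentq

    p = params or RWWParams()

    def g(S: float) -> float:
        H = firing_rate(p.omega * p.J_N * S + p.I_0, p)
        return -S / p.tau_s + (1.0 - S) * p.gamma_kin * H

    return float(brentq(g, 0.0, 1.0, xtol=1e-12))
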