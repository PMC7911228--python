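"""Leaky integrate-and-fire membrane dynamics.

The membrane potential ``u`` of a LIF neuron obeys

    tau_m * du/dt = -(u - E_L) + R * I(t)

with a spike emitted when ``u`` reaches the threshold ``V_th``, an
instantaneous reset to ``V_reset``, and an absolute refractory period
``t_ref`` during which the membrane is clamped at ``V_reset``.

Integration uses the *exact* solution for piecewise-constant input over each
time step, written in the increment form

    u' = u + (u_inf - u) * (1 - exp(-dt/tau_m)),   u_inf = E_L + R * I,

which is algebraically identical to the textbook exponential update but, in
floating point, approaches the fixed point strictly monotonically from below:
a neuron driven at exactly its rheobase current never reaches threshold, at
any simulation length.  Spike times are recorded on step boundaries (the end
of the step in which the crossing occurs); there is no within-step
interpolation.

Units throughout: mV (potentials), pA (currents), ms (times), pF
(capacitance), MOhm (resistance).  Note MOhm * pA = uV, hence the 1e-3
factors wherever R multiplies a current.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LIFParams",
    "NeuronState",
    "step",
    "rheobase",
    "closed_form_potential",
    "time_to_first_spike",
    "simulate_constant_current",
    "LIFLayer",
]


@dataclass(frozen=True)
class LIFParams:
    """Membrane constants of a leaky integrate-and-fire neuron.

    Defaults are the NEST ``iaf`` defaults used throughout: tau_m = 10 ms,
    C_m = 250 pF, E_L = V_reset = -70 mV, V_th = -55 mV, giving a membrane
    resistance R = tau_m / C_m = 40 MOhm and a rheobase of 375 pA.
    """

    tau_m: float = 10.0   # membrane time constant, ms
    C_m: float = 250.0    # membrane capacitance, pF
    E_L: float = -70.0    # resting potential, mV
    V_th: float = -55.0   # spike threshold, mV
    V_reset: float = -70.0  # reset potential, mV
    t_ref: float = 2.0    # absolute refractory period, ms

    def __post_init__(self) -> None:
        if self.tau_m <= 0 or self.C_m <= 0:
            raise ValueError("tau_m and C_m must be positive")
        if self.t_ref < 0:
            raise ValueError("t_ref must be non-negative")
        if self.V_reset > self.V_th:
            raise ValueError("V_reset must not exceed V_th")
        if self.E_L >= self.V_th:
            raise ValueError("E_L must lie below V_th")

    @property
    def R(self) -> float:
        """Membrane resistance tau_m / C_m, in MOhm (1/g_leak)."""
        return 1e3 * self.tau_m / self.C_m

    def u_inf(self, I: float | np.ndarray) -> float | np.ndarray:
        """Fixed point E_L + R*I of the membrane equation for current I [pA]."""
        return self.E_L + self.R * 1e-3 * I

    @classmethod
    def from_config(cls, cfg: dict) -> "LIFParams":
        """Build from a mapping using either field names or the NEST-style
        aliases ``EL``, ``Vth``, ``Vreset``, ``Cm``, ``tau_m``, ``t_ref``."""
        alias = {"EL": "E_L", "Vth": "V_th", "Vreset": "V_reset", "Cm": "C_m"}
        kwargs = {}
        for key, value in cfg.items():
            name = alias.get(key, key)
            if name in cls.__dataclass_fields__:
                kwargs[name] = float(value)
        return cls(**kwargs)


@dataclass
class NeuronState:
    """Mutable state of one neuron: membrane potential, refractory clock,
    and the spike train emitted so far (ms, strictly increasing)."""

    u: float
    refractory_until: float = -math.inf
    spikes: list = field(default_factory=list)


def rheobase(params: LIFParams) -> float:
    """Minimal constant current [pA] whose fixed point reaches threshold.

    C_m * (V_th - E_L) / tau_m; 375 pA with default parameters.  At exactly
    this current the fixed point equals V_th and the membrane approaches it
    strictly from below, so the neuron never fires.
    """
    return params.C_m * (params.V_th - params.E_L) / params.tau_m


def closed_form_potential(params: LIFParams, u0: float, I: float, t) -> float:
    """Analytic subthreshold membrane potential at time t for constant I.

    u(t) = E_L + R*I + (u0 - E_L - R*I) * exp(-t / tau_m).  Valid while no
    spike has occurred; serves as the independent oracle for the stepper.
    """
    u_inf = params.u_inf(I)
    return u_inf + (u0 - u_inf) * np.exp(-np.asarray(t, dtype=float) / params.tau_m)


def time_to_first_spike(params: LIFParams, I: float, u0: float | None = None) -> float:
    """Analytic time [ms] for constant suprathreshold I to reach threshold.

    Returns ``inf`` if the fixed point does not exceed the threshold.
    """
    u0 = params.E_L if u0 is None else u0
    u_inf = params.u_inf(I)
    if u_inf <= params.V_th:
        return math.inf
    return params.tau_m * math.log((u_inf - u0) / (u_inf - params.V_th))


def step(state: NeuronState, params: LIFParams, I: float, dt: float,
         now: float) -> NeuronState:
    """Advance one neuron by ``dt`` under current ``I`` held constant on
    ``[now, now+dt)``; returns a new :class:`NeuronState`.

    The threshold test ``u >= V_th`` is applied at the step boundary
    ``now + dt``; a crossing appends a spike there, resets the membrane and
    starts the refractory clamp.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    new = NeuronState(u=state.u, refractory_until=state.refractory_until,
                      spikes=list(state.spikes))
    if now < state.refractory_until - 1e-12:
        new.u = params.V_reset
        return new
    u_inf = params.u_inf(I)
    u_next = state.u + (u_inf - state.u) * (-math.expm1(-dt / params.tau_m))
    t_next = now + dt
    if u_next >= params.V_th:
        new.spikes.append(t_next)
        new.u = params.V_reset
        new.refractory_until = t_next + params.t_ref
    else:
        new.u = u_next
    return new


def simulate_constant_current(params: LIFParams, I: float, duration: float,
                              dt: float = 0.1, u0: float | None = None):
    """Step a single neuron under constant current for ``duration`` ms.

    Returns ``(spike_times, u_final)``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    layer = LIFLayer(1, params, dt, u0=None if u0 is None else np.array([u0]))
    n_steps = int(round(duration / dt))
    drive = np.full((n_steps, 1), float(I))
    raster, _ = layer.run(drive)
    times = np.nonzero(raster[:, 0])[0] * dt
    return times, float(layer.u[0])


class LIFLayer:
    """A vector of identical LIF neurons stepped in lockstep.

    Holds membrane potentials, per-neuron refractory counters (in steps) and
    the running boundary index, so simulations can be continued across
    presentation windows without state resets.  ``shape`` may be an int or a
    tuple (e.g. ``(batch, n)``); all drive arrays must broadcast to it.
    """

    def __init__(self, shape, params: LIFParams, dt: float, u0=None):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.params = params
        self.dt = float(dt)
        self.shape = (shape,) if np.isscalar(shape) else tuple(shape)
        self.u = np.full(self.shape, params.E_L, dtype=float)
        if u0 is not None:
            self.u[...] = np.broadcast_to(np.asarray(u0, dtype=float), self.shape)
        self.refr = np.zeros(self.shape, dtype=np.int64)
        self.boundary = 0  # global index; boundary b is at time b*dt
        self._refr_steps = int(math.ceil(params.t_ref / dt - 1e-9))
        self._decay_c = -math.expm1(-dt / params.tau_m)  # 1 - exp(-dt/tau)
        self._r = params.R * 1e-3  # mV per pA

    def run(self, drive: np.ndarray, forced: np.ndarray | None = None):
        """Advance ``n_steps = drive.shape[0]`` steps.

        ``drive[s]`` is the total injected current [pA] during step ``s``
        (from local boundary s to s+1), broadcastable to ``shape``.
        ``forced[s]``, if given, is a boolean mask of neurons that are forced
        to emit a relay spike at local boundary ``s`` (honoured only outside
        refractoriness).

        Returns ``(raster, t0)`` where ``raster`` is a boolean array of shape
        ``(n_steps + 1, *shape)`` marking spikes at local boundaries 0..n_steps
        (forced spikes at their boundary, threshold spikes at the end of the
        crossing step), and ``t0`` is the absolute time [ms] of local
        boundary 0.
        """
        n_steps = drive.shape[0]
        raster = np.zeros((n_steps + 1,) + self.shape, dtype=bool)
        t0 = self.boundary * self.dt
        u, refr = self.u, self.refr
        E_L, V_th, V_reset = self.params.E_L, self.params.V_th, self.params.V_reset
        c, r = self._decay_c, self._r
        for s in range(n_steps):
            if forced is not None:
                fire = forced[s] & (refr == 0)
                if fire.any():
                    raster[s] |= fire
                    u[fire] = V_reset
                    refr[fire] = self._refr_steps
            active = refr == 0
            u_inf = E_L + r * np.broadcast_to(drive[s], self.shape)
            u_new = u + (u_inf - u) * c
            u = np.where(active, u_new, V_reset)
            crossed = active & (u >= V_th)
            if crossed.any():
                raster[s + 1][crossed] = True
                u[crossed] = V_reset
            np.maximum(refr - 1, 0, out=refr, where=~crossed)
            refr[crossed] = self._refr_steps
        self.u, self.refr = u, refr
        self.boundary += n_steps
        return raster, t0
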