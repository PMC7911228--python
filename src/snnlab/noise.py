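"""Gaussian white-noise current generators.

Each generator emits a piecewise-constant current: at every refresh interval
(by default the simulation step) a fresh value

    I_k = mu + sigma * eta_k,    eta_k ~ N(0, 1) i.i.d.

is drawn and held for the interval.  This copies the semantics of the NEST
``noise_generator`` device that the surrogate background-activity model is
built on: draws are indexed per tick and are NOT scaled by 1/sqrt(dt), so the
effective variance of the injected charge depends on the refresh interval.
This deviates on purpose from a true Wiener-process discretisation and is the
convention assumed everywhere in this package (see docs/methods.md).

With ``sigma = 0`` the generator degenerates to a constant ``mu`` and the
whole simulation reduces exactly to the deterministic membrane equation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["NoiseParams", "NoiseGenerator", "NoiseBank",
           "draw_current_trace", "generator_bank"]


@dataclass(frozen=True)
class NoiseParams:
    """Mean/spread of the Gaussian current generator, in pA."""

    mu: float = 0.0
    sigma: float = 0.0
    refresh_dt: float = 0.1  # ms; a fresh value per simulation step
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.refresh_dt <= 0:
            raise ValueError("refresh_dt must be positive")

    @classmethod
    def from_config(cls, cfg: dict) -> "NoiseParams":
        alias = {"mean_pA": "mu", "std_pA": "sigma"}
        kwargs = {alias.get(k, k): v for k, v in cfg.items()
                  if alias.get(k, k) in cls.__dataclass_fields__}
        return cls(**kwargs)


class NoiseGenerator:
    """One seeded noise stream; draws persist across successive calls so a
    simulation can be continued window by window."""

    def __init__(self, params: NoiseParams):
        self.params = params
        self._rng = np.random.default_rng(params.seed)

    def draw(self, n: int) -> np.ndarray:
        """Next ``n`` current values [pA]."""
        p = self.params
        if p.sigma == 0.0:
            return np.full(n, p.mu)
        return p.mu + p.sigma * self._rng.standard_normal(n)


def draw_current_trace(params: NoiseParams, duration: float) -> np.ndarray:
    """One current value [pA] per refresh interval covering ``duration`` ms."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(math.ceil(duration / params.refresh_dt - 1e-9))
    return NoiseGenerator(params).draw(n)


class NoiseBank:
    """``n`` independent generators (one per attached neuron), with child
    seed streams spawned from ``params.seed``.  ``draw(n_steps)`` returns an
    ``(n_steps, n)`` matrix of currents, column ``j`` coming from neuron
    ``j``'s own stream; successive calls continue the streams."""

    def __init__(self, params: NoiseParams, n: int):
        self.params = params
        self.n = n
        children = np.random.SeedSequence(params.seed).spawn(n)
        self._rngs = [np.random.default_rng(c) for c in children]

    def draw(self, n_steps: int) -> np.ndarray:
        p = self.params
        if p.sigma == 0.0:
            return np.full((n_steps, self.n), p.mu)
        cols = [rng.standard_normal(n_steps) for rng in self._rngs]
        return p.mu + p.sigma * np.stack(cols, axis=1)


def generator_bank(params: NoiseParams, n: int) -> NoiseBank:
    """Convenience constructor for :class:`NoiseBank`."""
    return NoiseBank(params, n)
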