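"""Coincidence-gated growth of lateral memory-layer synapses.

Growth follows a minimal temporal Hebbian reading — "cells that fire in
causal order, wire": for every ordered pair (i, j) of memory neurons whose
grid positions lie within a Chebyshev neighbourhood, the number of spike
pairs with ``0 < t_j - t_i <= coincidence_window`` inside one presentation
window is counted; reaching ``coincidence_threshold`` creates the synapse
i -> j at ``initial_weight``.  Synapses are only ever added, never removed,
and grown synapses are structural records: they do not inject current
during the growth run (the experiment observes growth, it does not feed it
back).

The three observation conditions mirror the memory-layer experiment:

    a) stimulus only — images drive the memory layer, no noise;
    b) noise only   — no images, suprathreshold Gaussian-mean drive
       (mu = 400 pA, sigma = 0) on a random ~20% subset of neurons;
    c) stimulus + noise.

Subthreshold noise (e.g. mu = 300 pA < 375 pA rheobase) cannot excite any
neuron in condition (b), so exactly zero synapses grow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .encoding import encode_pixel, preprocess
from .lif import LIFLayer
from .noise import NoiseParams
from .network import NetworkSpec, build_three_layer
from .stdp import SynapseMatrix

__all__ = ["GrowthRule", "GrowthReport", "grid_coordinates", "neighbor_mask",
           "grow_step", "run_growth_experiment"]


@dataclass(frozen=True)
class GrowthRule:
    """Parameters of the coincidence rule.

    ``coincidence_window`` [ms] bounds the causal lag; ``neighborhood_radius``
    is a Chebyshev distance on the (row, col) grid (feature channels sit at
    the same spatial position, i.e. at distance zero from one another).
    """

    coincidence_window: float = 10.0
    coincidence_threshold: int = 1
    neighborhood_radius: int = 3
    initial_weight: float = 0.5

    def __post_init__(self) -> None:
        if self.coincidence_window <= 0:
            raise ValueError("coincidence_window must be positive")
        if self.coincidence_threshold < 1:
            raise ValueError("coincidence_threshold must be >= 1")
        if self.neighborhood_radius < 1:
            raise ValueError("neighborhood_radius must be >= 1")


@dataclass
class GrowthReport:
    """Outcome of one growth run: synapse count, per-synapse coordinate map
    and the noise-attachment map on the (channel, row, col) memory grid."""

    condition: str
    n_synapses: int
    synapse_map: list
    noise_attachment_map: list
    incident_synapses: np.ndarray  # per-neuron grown in+out degree
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "n_synapses": self.n_synapses,
            "synapse_map": [[list(a), list(b)] for a, b in self.synapse_map],
            "noise_attachment_map": [list(c) for c in self.noise_attachment_map],
            "incident_synapses": self.incident_synapses.tolist(),
            "seed": self.seed,
        }


def grid_coordinates(n_filters: int, side: int) -> np.ndarray:
    """(n, 3) array of (channel, row, col) for the flattened memory grid."""
    ch, r, c = np.unravel_index(np.arange(n_filters * side * side),
                                (n_filters, side, side))
    return np.stack([ch, r, c], axis=1)


def neighbor_mask(coords: np.ndarray, radius: int) -> np.ndarray:
    """Boolean (n, n) mask of ordered pairs within Chebyshev ``radius`` on
    (row, col); self-pairs excluded."""
    rc = coords[:, -2:]
    d = np.abs(rc[:, None, :] - rc[None, :, :]).max(axis=2)
    mask = d <= radius
    np.fill_diagonal(mask, False)
    return mask


def _coincidence_counts(trains, window: float) -> np.ndarray:
    """(n, n) matrix of causal coincidence counts between all neuron pairs;
    entry (i, j) counts spike pairs with 0 < t_j - t_i <= window."""
    trains = [np.atleast_1d(np.asarray(t, dtype=float)) for t in trains]
    n = len(trains)
    k = max((t.size for t in trains), default=0)
    if k == 0:
        return np.zeros((n, n), dtype=np.int64)
    T = np.full((n, k), np.nan)
    for i, t in enumerate(trains):
        T[i, : t.size] = t
    counts = np.zeros((n, n), dtype=np.int64)
    for a in range(k):        # pre spike slot
        for b in range(k):    # post spike slot
            d = T[None, :, b] - T[:, None, a]
            counts += (d > 0) & (d <= window)
    return counts


def grow_step(memory_spikes, existing: SynapseMatrix, rule: GrowthRule,
              coords: np.ndarray) -> SynapseMatrix:
    """Apply one presentation window's growth to ``existing`` (in place).

    ``memory_spikes`` is one spike-time array per memory neuron (times from
    a single presentation window); ``coords`` the per-neuron grid
    coordinates.  New synapses appear where the causal coincidence count
    within the neighbourhood reaches the threshold; nothing is ever removed.
    """
    counts = _coincidence_counts(memory_spikes, rule.coincidence_window)
    eligible = (neighbor_mask(coords, rule.neighborhood_radius)
                & ~existing.mask & (counts >= rule.coincidence_threshold))
    existing.mask |= eligible
    existing.weights[eligible] = rule.initial_weight
    return existing


def _window_trains(raster: np.ndarray, t0: float, dt: float) -> list:
    """Spike times per neuron from one window's raster (boundaries 0..S;
    boundary 0 carries only relay spikes of this window)."""
    return [t0 + np.nonzero(raster[:, i])[0] * dt
            for i in range(raster.shape[1])]


def run_growth_experiment(condition: str, dataset, noise: NoiseParams | None = None,
                          n_presentations: int = 30, seed: int = 0, *,
                          rule: GrowthRule | None = None,
                          n_noise: int = 120,
                          net: NetworkSpec | None = None) -> GrowthReport:
    """Run one condition of the memory-layer growth experiment.

    Builds the three-layer network (unless ``net`` is supplied), simulates
    ``n_presentations`` consecutive presentation windows in continuous time
    (membrane state carries across windows, so suprathreshold noise cycles
    freely through charge/fire/reset), and applies :func:`grow_step` after
    each window.  Condition "b" ignores the dataset.
    """
    if condition not in ("a", "b", "c"):
        raise ValueError("condition must be 'a', 'b' or 'c'")
    rule = rule or GrowthRule()
    noise = noise or NoiseParams(mu=400.0, sigma=0.0)
    if net is None:
        # the attachment subset is drawn identically in every condition (same
        # seed, same draw order); condition "a" simply never injects from it
        net = build_three_layer(noise=noise if condition != "a" else None,
                                n_noise=n_noise, seed=seed)
    side = int(math.isqrt(net.n_in // net.n_filters))
    coords = grid_coordinates(net.n_filters, side)
    nbr_cache = neighbor_mask(coords, rule.neighborhood_radius)
    lateral = net.lateral if net.lateral is not None else SynapseMatrix(
        np.zeros((net.n_in, net.n_in)), np.zeros((net.n_in, net.n_in), bool))
    use_images = condition in ("a", "c")
    use_noise = condition in ("b", "c") and net.noise_idx is not None
    if use_images and (dataset is None or len(dataset) == 0):
        raise ValueError(f"condition {condition!r} requires a dataset")
    steps_per_window = int(round(net.encoding.pitch / net.dt))
    layer = LIFLayer(net.n_in, net.lif, net.dt, u0=net.u0_mem)
    value_to_step = np.ceil(
        encode_pixel(np.arange(256.0), net.encoding) / net.dt - 1e-9
    ).astype(np.int64)
    # background below the encoding cutoff is tailored away (never spikes)
    value_to_step[np.arange(256.0) < net.encoding.cutoff_value] = 10 ** 9
    for w in range(n_presentations):
        forced = None
        if use_images:
            img = dataset.images[w % len(dataset)]
            feats = preprocess(img, net.n_filters, pooling=net.pooling)
            steps = value_to_step[np.clip(feats.ravel(), 0, 255).astype(np.int64)]
            forced = np.zeros((steps_per_window, net.n_in), dtype=bool)
            inside = steps < steps_per_window
            forced[steps[inside], np.nonzero(inside)[0]] = True
        drive = np.zeros((steps_per_window, net.n_in))
        if use_noise:
            drive[:, net.noise_idx] = (net.noise_bank.draw(steps_per_window)
                                       if net.noise_bank is not None
                                       else noise.mu)
        raster, t0 = layer.run(drive, forced)
        # the final boundary's threshold spikes belong to this window; the
        # next window's boundary 0 can only carry (refractory-gated) relay
        # spikes, so no event is ever counted twice
        trains = _window_trains(raster, t0, net.dt)
        counts = _coincidence_counts(trains, rule.coincidence_window)
        eligible = nbr_cache & ~lateral.mask & (counts >= rule.coincidence_threshold)
        lateral.mask |= eligible
        lateral.weights[eligible] = rule.initial_weight
    pre_idx, post_idx = np.nonzero(lateral.mask)
    synapse_map = [(tuple(int(x) for x in coords[i]),
                    tuple(int(x) for x in coords[j]))
                   for i, j in zip(pre_idx, post_idx)]
    incident = np.bincount(pre_idx, minlength=net.n_in) + np.bincount(
        post_idx, minlength=net.n_in)
    noise_map = [tuple(int(x) for x in coords[i])
                 for i in (net.noise_idx if net.noise_idx is not None else [])]
    return GrowthReport(condition=condition, n_synapses=len(synapse_map),
                        synapse_map=synapse_map, noise_attachment_map=noise_map,
                        incident_synapses=incident, seed=seed)
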