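"""Two- and three-layer noisy SNNs: wiring, presentation loop, decoding.

Two-layer network: each pixel of a 28x28 image drives one *relay* input
neuron, which emits exactly one spike at the pixel's encoded latency
(regardless of its membrane state — this keeps the latency code exact at
layer 1).  Every input neuron additionally owns a private Gaussian noise
generator; noise can only add spikes if it drives the membrane over
threshold (i.e. at suprathreshold mean or nonzero sigma).  The 10 output
neurons are fully connected to the inputs through plastic synapses and
integrate weighted delta-current pulses: a presynaptic spike injects
``w * I_syn`` pA for one simulation step into each postsynaptic target.

Decoding is rank-order: the output neuron with the earliest spike wins;
ties break to the larger spike count, then to the lowest index.  If no
output spikes at all, the prediction falls back to label 0 and is flagged.

The three-layer network inserts a 576-neuron memory layer (four 12x12
conv/pool feature maps, latency-encoded the same way) between input and
output; a seeded random subset of memory neurons carries noise generators.
Its lateral synapses start empty (or from a sparse preexisting mask) and are
grown by :mod:`snnlab.growth`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .encoding import EncodedImage, EncodingParams, conv_kernels, encode_image, preprocess
from .lif import LIFLayer, LIFParams, rheobase
from .noise import NoiseBank, NoiseParams
from .stdp import STDPParams, SynapseMatrix, supervised_update

__all__ = [
    "NetworkSpec",
    "Prediction",
    "build_two_layer",
    "build_three_layer",
    "present",
    "train",
    "evaluate",
    "predict_batch",
]


@dataclass
class Prediction:
    label: int
    per_output_spike_counts: np.ndarray
    first_spike_times: np.ndarray
    no_spike: bool = False


@dataclass
class NetworkSpec:
    """A wired network plus every parameter needed to simulate it."""

    kind: str
    image_shape: tuple
    n_in: int
    n_out: int
    synapses: SynapseMatrix
    lif: LIFParams
    stdp: STDPParams
    encoding: EncodingParams
    noise: NoiseParams | None
    dt: float
    I_syn: float
    seed: int
    noise_idx: np.ndarray | None = None      # neurons carrying a generator
    noise_bank: NoiseBank | None = None
    n_filters: int = 1
    pooling: str = "max"
    lateral: SynapseMatrix | None = None     # memory-layer structural synapses
    u0_mem: np.ndarray | None = None         # initial memory-layer membranes

    @property
    def layer_sizes(self) -> tuple:
        return (self.n_in, self.n_out)

    def noise_is_subthreshold(self) -> bool:
        """True when the attached noise provably cannot fire any neuron on
        its own (sigma = 0 and mean below rheobase), so relay spikes are the
        complete input-layer activity."""
        if self.noise is None:
            return True
        return self.noise.sigma == 0.0 and self.noise.mu < rheobase(self.lif)


def build_two_layer(image_shape=(28, 28), n_out: int = 10,
                    noise: NoiseParams | None = None, *, seed: int = 0,
                    lif: LIFParams | None = None,
                    stdp: STDPParams | None = None,
                    encoding: EncodingParams | None = None,
                    dt: float = 0.1, I_syn: float = 1200.0,
                    w_init=(0.3, 0.7)) -> NetworkSpec:
    """Wire the pixel->output network: one relay neuron per pixel, one noise
    generator per relay neuron, all-to-all plastic projection to ``n_out``
    outputs with weights i.i.d. uniform on ``w_init``."""
    n_in = int(np.prod(image_shape))
    rng = np.random.default_rng(seed)
    synapses = SynapseMatrix.random_uniform(n_in, n_out, rng, *w_init)
    net = NetworkSpec(
        kind="two_layer", image_shape=tuple(image_shape), n_in=n_in,
        n_out=n_out, synapses=synapses, lif=lif or LIFParams(),
        stdp=stdp or STDPParams(), encoding=encoding or EncodingParams(),
        noise=noise, dt=dt, I_syn=I_syn, seed=seed,
        noise_idx=np.arange(n_in) if noise is not None else None,
    )
    if noise is not None:
        net.noise_bank = NoiseBank(noise, n_in)
    return net


def build_three_layer(image_shape=(28, 28), n_filters: int = 4,
                      n_out: int = 10, noise: NoiseParams | None = None,
                      noise_fraction: float = 0.2, *, n_noise: int | None = None,
                      seed: int = 0, lif: LIFParams | None = None,
                      stdp: STDPParams | None = None,
                      encoding: EncodingParams | None = None,
                      dt: float = 0.1, I_syn: float = 1200.0,
                      pooling: str = "max", spread_initial_u: bool = True,
                      preexisting_density: float = 0.0) -> NetworkSpec:
    """Wire the conv/pool -> memory -> output network.

    The memory layer holds one neuron per preprocessed pixel
    (``n_filters * 12 * 12`` for 28x28 input); ``round(noise_fraction *
    n_mem)`` generators — or exactly ``n_noise`` if given — attach to a
    seeded random subset of memory neurons.  Memory membranes start spread
    uniformly over [E_L, V_th) (heterogeneous initial states; disable with
    ``spread_initial_u=False``), and lateral synapses start from an optional
    random sparse preexisting mask (default: none).
    """
    if not 0.0 <= noise_fraction <= 1.0:
        raise ValueError("noise_fraction must lie in [0, 1]")
    lif = lif or LIFParams()
    side = (image_shape[0] - 4 + 1) // 2
    n_mem = n_filters * side * side
    rng = np.random.default_rng(seed)
    synapses = SynapseMatrix.random_uniform(n_mem, n_out, rng)
    k = int(round(noise_fraction * n_mem)) if n_noise is None else int(n_noise)
    noise_idx = np.sort(rng.choice(n_mem, size=k, replace=False)) if k else np.array([], dtype=int)
    lateral_mask = np.zeros((n_mem, n_mem), dtype=bool)
    if preexisting_density > 0:
        lateral_mask = rng.random((n_mem, n_mem)) < preexisting_density
        np.fill_diagonal(lateral_mask, False)
    lateral = SynapseMatrix(weights=np.where(lateral_mask, 0.5, 0.0),
                            mask=lateral_mask)
    u0 = rng.uniform(lif.E_L, lif.V_th, size=n_mem) if spread_initial_u else None
    net = NetworkSpec(
        kind="three_layer", image_shape=tuple(image_shape), n_in=n_mem,
        n_out=n_out, synapses=synapses, lif=lif, stdp=stdp or STDPParams(),
        encoding=encoding or EncodingParams(), noise=noise, dt=dt,
        I_syn=I_syn, seed=seed, noise_idx=noise_idx, n_filters=n_filters,
        pooling=pooling, lateral=lateral, u0_mem=u0,
    )
    if noise is not None and k:
        net.noise_bank = NoiseBank(noise, k)
    return net


_NEVER = 10 ** 9  # boundary index of a spike that never happens


def _forced_steps(net: NetworkSpec, encoded: EncodedImage) -> np.ndarray:
    """Encoded spike latencies -> step-boundary indices (first boundary at or
    after the analog latency); non-finite latencies (tailored-away
    background pixels) map to a far-out sentinel."""
    times = np.asarray(encoded.spike_times, dtype=float).ravel()
    if times.size != net.n_in:
        raise ValueError(
            f"encoded image has {times.size} pixels, network expects {net.n_in}")
    finite = np.isfinite(times)
    idx = np.full(times.shape, _NEVER, dtype=np.int64)
    idx[finite] = np.ceil(times[finite] / net.dt - 1e-9).astype(np.int64)
    return idx


def _n_steps(net: NetworkSpec, duration: float | None) -> int:
    duration = net.encoding.pitch if duration is None else duration
    return int(round(duration / net.dt))


def _input_spike_trains(net: NetworkSpec, forced_idx: np.ndarray,
                        n_steps: int):
    """Input-layer spike times for one presentation.

    Fast path: with provably subthreshold noise, the relay schedule *is* the
    complete activity, so membranes need not be stepped.  Otherwise the input
    layer is simulated with its per-neuron noise streams and forced relay
    spikes, and the full raster is returned.
    """
    if net.noise_is_subthreshold():
        return (forced_idx * net.dt)[:, None], None
    forced = np.zeros((n_steps, net.n_in), dtype=bool)
    inside = forced_idx < n_steps
    forced[forced_idx[inside], np.nonzero(inside)[0]] = True
    drive = np.zeros((n_steps, net.n_in))
    drive[:, net.noise_idx] = net.noise_bank.draw(n_steps)
    layer = LIFLayer(net.n_in, net.lif, net.dt)
    raster, _ = layer.run(drive, forced)
    trains = _raster_to_padded(raster, net.dt)
    return trains, raster


def _raster_to_padded(raster: np.ndarray, dt: float) -> np.ndarray:
    """Boolean raster (n_boundaries, n) -> NaN-padded (n, k_max) spike-time
    matrix."""
    counts = raster.sum(axis=0)
    k = max(int(counts.max()), 1)
    n = raster.shape[1]
    out = np.full((n, k), np.nan)
    b_idx, n_idx = np.nonzero(raster)
    order = np.lexsort((b_idx, n_idx))
    b_idx, n_idx = b_idx[order], n_idx[order]
    slot = np.concatenate([np.arange(c) for c in counts]) if b_idx.size else np.array([], int)
    out[n_idx, slot] = b_idx * dt
    return out


def _output_drive(net: NetworkSpec, spike_steps: np.ndarray,
                  weights: np.ndarray, n_steps: int) -> np.ndarray:
    """Per-step synaptic current into each output neuron [pA].

    ``spike_steps`` holds one boundary index per input neuron (the fast
    path's single relay spike); a spike at boundary s injects its pulse
    during step s, so the earliest possible postsynaptic spike is boundary
    s+1 (strictly causal).
    """
    drive = np.zeros((n_steps + 1, weights.shape[1]))
    np.add.at(drive, np.minimum(spike_steps, n_steps), weights * net.I_syn)
    return drive[:n_steps]


def _simulate_single(net: NetworkSpec, encoded: EncodedImage,
                     duration: float | None = None,
                     teacher: tuple[int, float] | None = None):
    """One presentation; returns (pre_trains, post_trains, raster_out).

    ``teacher``, used only while training, is a ``(label, latency_ms)`` pair
    forcing a supervising spike on the true output neuron: it guarantees the
    matched column keeps receiving causal potentiation even when its natural
    drive has (transiently) fallen below threshold.
    """
    n_steps = _n_steps(net, duration)
    forced_idx = _forced_steps(net, encoded)
    if net.noise_is_subthreshold():
        pre_trains = np.where(forced_idx < _NEVER,
                              forced_idx * net.dt, np.nan)[:, None]
        drive = _output_drive(net, forced_idx, net.synapses.weights, n_steps)
    else:
        pre_trains, raster_in = _input_spike_trains(net, forced_idx, n_steps)
        drive = raster_in[:n_steps].astype(float) @ (net.synapses.weights * net.I_syn)
    forced_out = None
    if teacher is not None:
        label, latency = teacher
        forced_out = np.zeros((n_steps, net.n_out), dtype=bool)
        forced_out[min(int(np.ceil(latency / net.dt - 1e-9)), n_steps - 1),
                   label] = True
    out_layer = LIFLayer(net.n_out, net.lif, net.dt)
    raster_out, _ = out_layer.run(drive, forced_out)
    post_trains = [np.nonzero(raster_out[:, j])[0] * net.dt
                   for j in range(net.n_out)]
    return pre_trains, post_trains, raster_out


def _decode(first_times: np.ndarray, counts: np.ndarray) -> tuple[int, bool]:
    if not np.isfinite(first_times).any():
        return 0, True
    order = np.lexsort((np.arange(len(first_times)), -counts, first_times))
    return int(order[0]), False


def present(net: NetworkSpec, encoded: EncodedImage | np.ndarray,
            duration: float | None = None) -> Prediction:
    """Run one stimulus presentation and decode the predicted label."""
    if isinstance(encoded, np.ndarray):
        encoded = EncodedImage(spike_times=encoded)
    _, post_trains, _ = _simulate_single(net, encoded, duration)
    first = np.array([t[0] if t.size else math.inf for t in post_trains])
    counts = np.array([t.size for t in post_trains])
    label, silent = _decode(first, counts)
    return Prediction(label=label, per_output_spike_counts=counts,
                      first_spike_times=first, no_spike=silent)


def _encode_for_network(net: NetworkSpec, image: np.ndarray) -> EncodedImage:
    """Image -> spike latencies matching the network's first plastic layer
    (raw pixels for the two-layer net, conv/pool features for the
    three-layer net).  Background pixels below the encoding cutoff are
    tailored away: their latency is set to +inf, i.e. they never spike."""
    values = np.asarray(image, dtype=float)
    if net.kind == "three_layer":
        values = preprocess(values, net.n_filters, pooling=net.pooling)
    times = np.asarray(encode_image(values, net.encoding).spike_times, float)
    times = np.where(values >= net.encoding.cutoff_value, times, np.inf)
    return EncodedImage(spike_times=times)


def predict_batch(net: NetworkSpec, images: np.ndarray) -> np.ndarray:
    """Predicted labels for a stack of images (weights held fixed).

    Uses a batched presentation loop; falls back to one-by-one simulation
    when input-layer noise can fire on its own.
    """
    images = np.asarray(images, dtype=float)
    if not net.noise_is_subthreshold():
        return np.array([present(net, _encode_for_network(net, img)).label
                         for img in images])
    n_steps = _n_steps(net, None)
    B = len(images)
    idx = np.stack([_forced_steps(net, _encode_for_network(net, img))
                    for img in images])  # (B, n_in)
    WI = net.synapses.weights * net.I_syn  # (n_in, n_out)
    drive = np.zeros((n_steps + 1, B, net.n_out))
    for b in range(B):
        np.add.at(drive[:, b], np.minimum(idx[b], n_steps), WI)
    layer = LIFLayer((B, net.n_out), net.lif, net.dt)
    raster, _ = layer.run(drive[:n_steps])  # (n_steps+1, B, n_out)
    any_spike = raster.any(axis=0)
    first = np.where(any_spike, raster.argmax(axis=0), np.inf)
    counts = raster.sum(axis=0)
    labels = np.empty(B, dtype=np.int64)
    for b in range(B):
        labels[b], _ = _decode(first[b], counts[b])
    return labels


def evaluate(net: NetworkSpec, images, labels) -> float:
    """Fraction of images decoded to their true label."""
    return float(np.mean(predict_batch(net, images) == np.asarray(labels)))


def train(net: NetworkSpec, dataset, n_iterations: int,
          test_set=None, teacher_latency: float | None = 1.0,
          ) -> tuple[NetworkSpec, list[dict]]:
    """Supervised STDP training loop.

    ``dataset`` is a :class:`snnlab.data.LabeledImageSet` (or an
    ``(images, labels)`` pair).  One iteration presents every sample once,
    applying the reward-modulated STDP update after each presentation; the
    log records train (and optionally held-out) accuracy after every
    iteration.  Weights are modified in place; the network is also returned.
    """
    images, labels = (dataset.images, dataset.labels) if hasattr(dataset, "images") else dataset
    images = np.asarray(images, dtype=float)
    labels = np.asarray(labels)
    if len(images) == 0:
        raise ValueError("dataset must not be empty")
    if n_iterations < 0:
        raise ValueError("n_iterations must be non-negative")
    log: list[dict] = []
    for it in range(n_iterations):
        for img, lab in zip(images, labels):
            encoded = _encode_for_network(net, img)
            teacher = (int(lab), teacher_latency) if teacher_latency is not None else None
            pre_trains, post_trains, _ = _simulate_single(net, encoded,
                                                          teacher=teacher)
            supervised_update(net.synapses, pre_trains, post_trains,
                              int(lab), net.stdp)
        entry = {"iteration": it + 1,
                 "train_acc": evaluate(net, images, labels)}
        if test_set is not None:
            entry["test_acc"] = evaluate(net, test_set.images, test_set.labels)
        log.append(entry)
    return net, log
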