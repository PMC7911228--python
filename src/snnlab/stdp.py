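"""Pair-based spike-timing-dependent plasticity with supervised modulation.

The weight change of a synapse accumulates the classic pair-based STDP
window over *all* pre/post spike pairs of one presentation:

    dw = sum_a sum_b f(t_post_b - t_pre_a)

    f(dt) =  A_plus  * exp(-dt / tau_plus)   if dt > 0   (LTP, causal)
          = -A_minus * exp( dt / tau_minus)  if dt < 0   (LTD, anticausal)
          =  0                               if dt == 0

Exactly coincident spikes carry no causal order, hence f(0) = 0.  Defaults
are the canonical pair-based values A_plus = 0.005, A_minus = 1.05 * A_plus,
tau_plus = tau_minus = 20 ms.

Supervision turns this into a reward-modulated rule: synapses onto the
true-label output neuron receive +dw (the raw pair sum, so anticausal
background input is still depressed), while synapses onto any *other* output
neuron that spiked during the presentation are penalised by -|dw|.  Weights
are hard-clipped to [w_min, w_max] after every update.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "STDPParams",
    "SynapseMatrix",
    "stdp_window",
    "pair_weight_change",
    "supervised_update",
]


@dataclass(frozen=True)
class STDPParams:
    A_plus: float = 0.005
    A_minus: float = 0.00525      # 1.05 * A_plus
    tau_plus: float = 20.0        # ms
    tau_minus: float = 20.0       # ms
    w_min: float = 0.0
    w_max: float = 1.0
    reward_matched: float = 1.0
    reward_mismatched: float = -1.0

    def __post_init__(self) -> None:
        if min(self.A_plus, self.A_minus, self.tau_plus, self.tau_minus) <= 0:
            raise ValueError("A± and tau± must be positive")
        if not self.w_min < self.w_max:
            raise ValueError("w_min must be below w_max")


@dataclass
class SynapseMatrix:
    """Dense weight matrix (pre x post) with a connectivity mask; weights of
    unconnected pairs are pinned at zero."""

    weights: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.mask is None:
            self.mask = np.ones_like(self.weights, dtype=bool)
        self.weights = np.where(self.mask, self.weights, 0.0)

    @property
    def shape(self):
        return self.weights.shape

    def clip(self, params: STDPParams) -> None:
        np.clip(self.weights, params.w_min, params.w_max, out=self.weights)
        self.weights[~self.mask] = 0.0

    @classmethod
    def random_uniform(cls, n_pre: int, n_post: int, rng,
                       low: float = 0.3, high: float = 0.7) -> "SynapseMatrix":
        return cls(weights=rng.uniform(low, high, size=(n_pre, n_post)))


def stdp_window(delta_t, params: STDPParams = STDPParams()):
    """The piecewise-exponential pair window f(dt); vectorised over dt [ms]."""
    dt = np.asarray(delta_t, dtype=float)
    with np.errstate(over="ignore"):
        ltp = params.A_plus * np.exp(-dt / params.tau_plus)
        ltd = -params.A_minus * np.exp(dt / params.tau_minus)
    out = np.where(dt > 0, ltp, np.where(dt < 0, ltd, 0.0))
    return float(out) if out.ndim == 0 else out


def pair_weight_change(pre, post, params: STDPParams = STDPParams()) -> float:
    """All-pairs double sum of the STDP window over one pre/post train pair."""
    pre = np.asarray(pre, dtype=float).ravel()
    post = np.asarray(post, dtype=float).ravel()
    if pre.size == 0 or post.size == 0:
        return 0.0
    return float(stdp_window(post[None, :] - pre[:, None], params).sum())


def _pad_trains(trains) -> np.ndarray:
    """Ragged list of spike-time arrays -> (n, k_max) float matrix padded
    with NaN (NaN pairs contribute zero to the pair sum)."""
    trains = [np.atleast_1d(np.asarray(t, dtype=float)) for t in trains]
    k = max((t.size for t in trains), default=0)
    out = np.full((len(trains), max(k, 1)), np.nan)
    for i, t in enumerate(trains):
        out[i, : t.size] = t
    return out


def _pair_sums_vs_post(pre_mat: np.ndarray, post: np.ndarray,
                       params: STDPParams) -> np.ndarray:
    """Vector of all-pairs sums between each padded pre train and one post
    train."""
    if post.size == 0:
        return np.zeros(pre_mat.shape[0])
    d = post[None, None, :] - pre_mat[:, :, None]  # (n_pre, k, n_post_spikes)
    f = stdp_window(d, params)
    return np.nansum(np.where(np.isnan(d), 0.0, f), axis=(1, 2))


def supervised_update(synapses: SynapseMatrix, pre_trains, post_trains,
                      true_label: int, params: STDPParams = STDPParams(),
                      ) -> SynapseMatrix:
    """Apply one presentation's reward-modulated STDP update in place.

    ``pre_trains``: one spike-time array per presynaptic (input) neuron;
    ``post_trains``: one spike-time array per output neuron.  Synapses onto
    the true-label neuron receive ``reward_matched * dw``; synapses onto any
    other neuron that spiked receive ``reward_mismatched * |dw|``.  Weights
    are clipped to [w_min, w_max] afterwards.  Returns ``synapses``.
    """
    n_post = synapses.shape[1]
    if not 0 <= true_label < n_post:
        raise ValueError(f"label {true_label} outside [0, {n_post})")
    if isinstance(pre_trains, np.ndarray) and pre_trains.ndim == 2:
        pre_mat = pre_trains  # already padded (n_pre, k), NaN-filled
    else:
        pre_mat = _pad_trains(pre_trains)
    if pre_mat.shape[0] != synapses.shape[0]:
        raise ValueError("pre_trains length does not match synapse matrix")
    for j in range(n_post):
        post = np.atleast_1d(np.asarray(post_trains[j], dtype=float))
        if j == true_label:
            dw = params.reward_matched * _pair_sums_vs_post(pre_mat, post, params)
        elif post.size > 0:
            dw = params.reward_mismatched * np.abs(
                _pair_sums_vs_post(pre_mat, post, params))
        else:
            continue
        synapses.weights[:, j] += np.where(synapses.mask[:, j], dw, 0.0)
    synapses.clip(params)
    return synapses
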