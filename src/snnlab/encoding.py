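"""Latency (rank-order) spike encoding and conv/pool image preprocessing.

A grayscale pixel value ``V`` in [0, 255] is mapped to a single spike time
inside a presentation window [T_start, T_stop]:

    S = (v - 1)^2 * (T_stop - T_start) + T_start,    v = V / 255,

a strictly decreasing bijection from pixel value onto the window: brighter
pixels fire earlier, and the latency law is steepest near the bright end, so
the most informative pixels are separated most finely in time.

For the three-layer experiments, 28x28 images are first passed through fixed
4x4 convolution kernels (stride 1, valid) and a 2x2 stride-2 pooling stage,
yielding 12x12 feature maps whose values are kept on the [0, 255] scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "EncodingParams",
    "EncodedImage",
    "encode_pixel",
    "encode_image",
    "decode_time",
    "conv_kernels",
    "preprocess",
    "LatencyEncoder",
    "ConvPoolPreprocessor",
]


@dataclass(frozen=True)
class EncodingParams:
    """Presentation window [T_start, T_stop] in ms, plus the silent gap
    appended after each presentation before the next one starts.

    ``cutoff_value`` tailors away uninformative background: pixels whose
    value falls strictly below it emit no spike at all when images drive a
    network (the pure value->latency map itself stays total).  The default
    of 1.0 silences only exact-zero background.
    """

    T_start: float = 0.0
    T_stop: float = 10.0
    gap: float = 5.0
    cutoff_value: float = 1.0

    def __post_init__(self) -> None:
        if not (self.T_stop > self.T_start >= 0):
            raise ValueError("need T_stop > T_start >= 0")
        if self.gap < 0:
            raise ValueError("gap must be non-negative")
        if not 0 <= self.cutoff_value <= 256:
            raise ValueError("cutoff_value must lie in [0, 256]")

    @property
    def window(self) -> float:
        return self.T_stop - self.T_start

    @property
    def pitch(self) -> float:
        """Time between successive presentation onsets."""
        return self.T_stop + self.gap


@dataclass(frozen=True)
class EncodedImage:
    """One spike time per pixel [ms], same shape as the source image."""

    spike_times: np.ndarray

    @property
    def shape(self):
        return self.spike_times.shape


def encode_pixel(value, params: EncodingParams = EncodingParams()):
    """Latency of the spike encoding pixel ``value`` in [0, 255]."""
    value = np.asarray(value, dtype=float)
    if np.any(value < 0) or np.any(value > 255):
        raise ValueError("pixel values must lie in [0, 255]")
    v = value / 255.0
    out = (v - 1.0) ** 2 * params.window + params.T_start
    return float(out) if out.ndim == 0 else out


def decode_time(t, params: EncodingParams = EncodingParams()):
    """Inverse of :func:`encode_pixel` (pixel value producing latency t)."""
    t = np.asarray(t, dtype=float)
    v = 1.0 - np.sqrt((t - params.T_start) / params.window)
    return 255.0 * v


def encode_image(image, params: EncodingParams = EncodingParams()) -> EncodedImage:
    """Elementwise latency encoding; one spike per pixel per presentation."""
    return EncodedImage(spike_times=encode_pixel(np.asarray(image), params))


def conv_kernels(n_filters: int = 4) -> np.ndarray:
    """The fixed 4x4 kernels: uniform average, horizontal-edge, vertical-edge
    and diagonal-edge detectors, in that order.

    Positive coefficients sum to 1 in every kernel, so outputs of inputs in
    [0, 255] never exceed 255; negative responses are clipped to 0
    downstream.
    """
    if not 1 <= n_filters <= 4:
        raise ValueError("n_filters must be between 1 and 4")
    avg = np.full((4, 4), 1 / 16)
    h_edge = np.vstack([np.full((2, 4), 1 / 8), np.full((2, 4), -1 / 8)])
    v_edge = h_edge.T.copy()
    ii, jj = np.indices((4, 4))
    diag = np.where((ii < 2) == (jj < 2), 1 / 8, -1 / 8)
    return np.stack([avg, h_edge, v_edge, diag])[:n_filters]


def _conv2d_valid(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Valid (no padding) stride-1 cross-correlation via stride tricks."""
    kh, kw = kernel.shape
    windows = np.lib.stride_tricks.sliding_window_view(image, (kh, kw))
    return np.einsum("ijkl,kl->ij", windows, kernel)


def _pool2x2(x: np.ndarray, mode: str) -> np.ndarray:
    """2x2 stride-2 pooling with floor truncation (odd trailing row/column
    dropped)."""
    h, w = (x.shape[0] // 2) * 2, (x.shape[1] // 2) * 2
    blocks = x[:h, :w].reshape(h // 2, 2, w // 2, 2)
    if mode == "max":
        return blocks.max(axis=(1, 3))
    if mode == "mean":
        return blocks.mean(axis=(1, 3))
    raise ValueError(f"unknown pooling mode {mode!r}")


def preprocess(image, n_filters: int = 4, kernels: np.ndarray | None = None,
               pooling: str = "max") -> np.ndarray:
    """4x4 stride-1 valid convolution then 2x2 stride-2 pooling.

    A 28x28 input becomes ``(n_filters, 12, 12)`` (25x25 after convolution,
    the 25th row/column dropped by the floor-truncating pool).  Outputs are
    clipped to [0, 255] so they can feed straight into the latency encoder.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be a 2-D array")
    if kernels is None:
        kernels = conv_kernels(n_filters)
    if len(kernels) != n_filters:
        raise ValueError("kernels/n_filters mismatch")
    channels = [
        _pool2x2(np.clip(_conv2d_valid(image, k), 0.0, 255.0), pooling)
        for k in kernels
    ]
    return np.stack(channels)


class LatencyEncoder(TransformerMixin, BaseEstimator):
    """Transformer mapping pixel arrays to spike-latency arrays.

    Stateless apart from parameter validation; ``transform`` applies the
    quadratic latency law elementwise, preserving input shape.
    """

    def __init__(self, T_start: float = 0.0, T_stop: float = 10.0):
        self.T_start = T_start
        self.T_stop = T_stop

    def fit(self, X, y=None):
        self.params_ = EncodingParams(self.T_start, self.T_stop)
        return self

    def transform(self, X):
        if not hasattr(self, "params_"):
            self.fit(X)
        return encode_pixel(np.asarray(X), self.params_)

    def inverse_transform(self, X):
        return decode_time(np.asarray(X), self.params_)


class ConvPoolPreprocessor(TransformerMixin, BaseEstimator):
    """Transformer applying the fixed conv/pool stage to stacks of images.

    Input of shape ``(n_samples, H, W)`` becomes
    ``(n_samples, n_filters, (H-3)//2, (W-3)//2)``.
    """

    def __init__(self, n_filters: int = 4, pooling: str = "max"):
        self.n_filters = n_filters
        self.pooling = pooling

    def fit(self, X, y=None):
        self.kernels_ = conv_kernels(self.n_filters)
        return self

    def transform(self, X):
        if not hasattr(self, "kernels_"):
            self.fit(X)
        X = np.asarray(X, dtype=float)
        single = X.ndim == 2
        if single:
            X = X[None]
        out = np.stack([
            preprocess(img, self.n_filters, self.kernels_, self.pooling)
            for img in X
        ])
        return out[0] if single else out
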