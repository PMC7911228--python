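"""scikit-learn estimator wrapping the supervised two-layer spiking network.

``SNNClassifier`` exposes the latency-coded, STDP-trained network through
the familiar fit/predict surface so it composes with sklearn pipelines and
model selection.  Images may be passed as ``(n, H, W)`` stacks or flattened
``(n, H*W)`` matrices with values in [0, 255].
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .encoding import EncodingParams
from .lif import LIFParams
from .network import build_two_layer, evaluate, predict_batch, train
from .noise import NoiseParams
from .stdp import STDPParams

__all__ = ["SNNClassifier"]


class SNNClassifier(ClassifierMixin, BaseEstimator):
    """Latency-coded LIF network classifier trained with supervised STDP.

    Parameters
    ----------
    mu, sigma : mean/sd [pA] of the per-input-neuron Gaussian noise current
        (``mu=0, sigma=0`` disables noise entirely).
    n_iterations : full passes over the training set.
    image_shape : spatial shape the flattened input is reshaped to.
    I_syn : synaptic pulse amplitude [pA] at weight 1.
    A_plus : STDP potentiation amplitude (depression is ``1.05 * A_plus``).
    dt : simulation resolution [ms].
    random_state : seed for weight initialisation and noise streams.

    Attributes
    ----------
    network_ : the trained :class:`snnlab.network.NetworkSpec`.
    weights_ : (n_pixels, n_classes) synaptic weight matrix after training.
    history_ : per-iteration accuracy log.
    classes_ : sorted class labels seen in ``fit``.
    """

    def __init__(self, mu: float = 0.0, sigma: float = 0.0,
                 n_iterations: int = 5, image_shape=(28, 28),
                 I_syn: float = 1200.0, A_plus: float = 0.02,
                 dt: float = 0.1, random_state: int = 0):
        self.mu = mu
        self.sigma = sigma
        self.n_iterations = n_iterations
        self.image_shape = image_shape
        self.I_syn = I_syn
        self.A_plus = A_plus
        self.dt = dt
        self.random_state = random_state

    def _as_images(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == int(np.prod(self.image_shape)):
            X = X.reshape((-1,) + tuple(self.image_shape))
        if X.ndim != 3:
            raise ValueError("X must be (n, H, W) images or (n, H*W) rows")
        return X

    def fit(self, X, y):
        X = self._as_images(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        n_out = max(10, int(self.classes_.max()) + 1) if np.issubdtype(
            self.classes_.dtype, np.integer) else len(self.classes_)
        noise = (NoiseParams(mu=self.mu, sigma=self.sigma, refresh_dt=self.dt,
                             seed=self.random_state)
                 if (self.mu or self.sigma) else None)
        stdp = STDPParams(A_plus=self.A_plus, A_minus=1.05 * self.A_plus)
        self.network_ = build_two_layer(
            image_shape=tuple(self.image_shape), n_out=n_out, noise=noise,
            seed=self.random_state, lif=LIFParams(), stdp=stdp,
            encoding=EncodingParams(), dt=self.dt, I_syn=self.I_syn)
        _, self.history_ = train(self.network_, (X, y), self.n_iterations)
        self.weights_ = self.network_.synapses.weights
        self.n_features_in_ = int(np.prod(self.image_shape))
        return self

    def predict(self, X):
        check_is_fitted(self, "network_")
        return predict_batch(self.network_, self._as_images(X))

    def score(self, X, y, sample_weight=None):
        check_is_fitted(self, "network_")
        return evaluate(self.network_, self._as_images(X), y)
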