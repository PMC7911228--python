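"""Network wiring, presentation/decoding, the training loop and the sklearn
estimator surface."""

import numpy as np
import pytest
from sklearn.base import clone

from snnlab import (EncodedImage, NoiseParams, SNNClassifier, STDPParams,
                    build_three_layer, build_two_layer, evaluate,
                    generate_digits, present, train)
from snnlab.network import _encode_for_network, _simulate_single

TOY_STDP = STDPParams(A_plus=0.05, A_minus=0.0525)

PATTERN_A = np.array([[255.0, 255.0], [0.0, 0.0]])
PATTERN_B = np.array([[0.0, 0.0], [255.0, 255.0]])


def toy_net(seed=0, **kwargs):
    kwargs.setdefault("I_syn", 40000.0)
    kwargs.setdefault("stdp", TOY_STDP)
    return build_two_layer(image_shape=(2, 2), n_out=2, seed=seed, **kwargs)


class TestWiring:
    def test_two_layer_counts(self):
        net = build_two_layer()
        assert net.layer_sizes == (784, 10)
        assert net.synapses.shape == (784, 10)          # 7840 synapses
        assert int(net.synapses.mask.sum()) == 7840

    def test_three_layer_memory_size_and_attachment(self):
        net = build_three_layer(n_noise=120, noise=NoiseParams(mu=400.0))
        assert net.n_in == 4 * 12 * 12 == 576
        assert net.noise_idx.size == 120
        net0 = build_three_layer(noise_fraction=0.0, n_noise=None)
        assert net0.noise_idx.size == 0

    def test_default_noise_fraction_rounds_to_115(self):
        net = build_three_layer(noise=NoiseParams(mu=400.0))
        assert net.noise_idx.size == round(0.2 * 576) == 115

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            build_three_layer(noise_fraction=1.5)


class TestPresentation:
    def test_zero_weights_yield_flagged_fallback(self):
        net = toy_net()
        net.synapses.weights[:] = 0.0
        pred = present(net, _encode_for_network(net, PATTERN_A))
        assert pred.label == 0 and pred.no_spike
        assert not np.isfinite(pred.first_spike_times).any()

    def test_saturated_output_wins(self):
        net = toy_net()
        net.synapses.weights[:] = 0.0
        net.synapses.weights[2:, 1] = 1.0  # row-two pixels -> output 1
        pred = present(net, _encode_for_network(net, PATTERN_B))
        assert pred.label == 1 and not pred.no_spike

    def test_geometry_mismatch_rejected(self):
        net = toy_net()
        with pytest.raises(ValueError):
            present(net, EncodedImage(np.zeros((3, 3))))

    def test_presentation_is_deterministic(self):
        net = toy_net(seed=3)
        enc = _encode_for_network(net, PATTERN_A)
        a, b = present(net, enc), present(net, enc)
        assert a.label == b.label
        np.testing.assert_array_equal(a.first_spike_times, b.first_spike_times)

    def test_every_input_spike_delivers_one_pulse_per_synapse(self):
        """Synaptic transmission conserves events: the summed output drive
        equals I_syn times the total afferent weight of the spiking inputs."""
        from snnlab.network import _forced_steps, _output_drive
        net = toy_net()
        enc = _encode_for_network(net, PATTERN_A)
        steps = _forced_steps(net, enc)
        drive = _output_drive(net, steps, net.synapses.weights, 150)
        spiking = steps < 150
        expected = net.I_syn * net.synapses.weights[spiking].sum()
        assert drive.sum() == pytest.approx(expected)


class TestTraining:
    def test_zero_iterations_keeps_weights(self):
        net = toy_net()
        before = net.synapses.weights.copy()
        _, log = train(net, (np.stack([PATTERN_A, PATTERN_B]), [0, 1]), 0)
        np.testing.assert_array_equal(net.synapses.weights, before)
        assert log == []

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train(toy_net(), (np.empty((0, 2, 2)), []), 1)

    def test_orthogonal_patterns_reach_perfect_accuracy(self):
        imgs = np.stack([PATTERN_A, PATTERN_B])
        labels = np.array([0, 1])
        net = toy_net()
        net, log = train(net, (imgs, labels), 20)
        assert log[-1]["train_acc"] == 1.0
        assert evaluate(net, imgs, labels) == 1.0

    def test_fixed_seed_reproduces_accuracy_log(self):
        ds = generate_digits(40, seed=5)
        logs = []
        for _ in range(2):
            net = build_two_layer(seed=5, stdp=STDPParams(A_plus=0.02,
                                                          A_minus=0.021))
            _, log = train(net, ds, 2)
            logs.append(log)
        assert logs[0] == logs[1]

    def test_teacher_spike_rescues_silent_matched_column(self):
        """With all weights at zero nothing fires naturally, yet the forced
        teaching spike still potentiates the true column."""
        net = toy_net()
        net.synapses.weights[:] = 0.0
        train(net, (PATTERN_A[None], [1]), 1, teacher_latency=1.0)
        assert net.synapses.weights[:2, 1].min() > 0.0


class TestClassifierEstimator:
    def test_sklearn_params_round_trip(self):
        clf = SNNClassifier(mu=8.0, n_iterations=2)
        assert clone(clf).get_params()["mu"] == 8.0
        clf.set_params(mu=4.0)
        assert clf.get_params()["mu"] == 4.0

    def test_fit_predict_score(self):
        ds = generate_digits(60, seed=0)
        clf = SNNClassifier(n_iterations=2, random_state=0)
        clf.fit(ds.images, ds.labels)
        preds = clf.predict(ds.images)
        assert preds.shape == (60,)
        assert clf.score(ds.images, ds.labels) > 2 * 0.1  # well above chance
        assert clf.weights_.shape == (784, 10)
        assert len(clf.history_) == 2

    def test_accepts_flattened_rows(self):
        ds = generate_digits(20, seed=1)
        clf = SNNClassifier(n_iterations=1, random_state=1)
        clf.fit(ds.images.reshape(20, -1), ds.labels)
        assert clf.predict(ds.images.reshape(20, -1)).shape == (20,)
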