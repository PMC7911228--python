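"""Pair-based STDP: window shape, all-pairs sums against a brute-force
oracle, linearity, and the supervised match/mismatch update."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from snnlab import (STDPParams, SynapseMatrix, pair_weight_change,
                    stdp_window, supervised_update)

DEFAULTS = STDPParams()


def brute_force_pair_sum(pre, post, p=DEFAULTS):
    total = 0.0
    for a in pre:
        for b in post:
            d = b - a
            if d > 0:
                total += p.A_plus * math.exp(-d / p.tau_plus)
            elif d < 0:
                total += -p.A_minus * math.exp(d / p.tau_minus)
    return total


class TestWindow:
    def test_decays_to_zero_at_infinity(self):
        assert stdp_window(1e6) == pytest.approx(0.0, abs=1e-300)
        assert stdp_window(-1e6) == pytest.approx(0.0, abs=1e-300)

    def test_simultaneous_spikes_carry_no_causal_order(self):
        assert stdp_window(0.0) == 0.0

    def test_point_values_at_one_time_constant(self):
        assert stdp_window(20.0) == pytest.approx(0.005 / math.e)
        assert stdp_window(-20.0) == pytest.approx(-0.00525 / math.e)

    def test_sign_encodes_ltp_vs_ltd(self):
        assert stdp_window(3.0) > 0      # causal -> potentiation
        assert stdp_window(-3.0) < 0     # anticausal -> depression

    @given(d=st.floats(0.1, 100.0))
    def test_anticausal_scale_at_equal_time_constants(self, d):
        """|f(-dt)| / f(dt) = A_minus / A_plus when tau_plus == tau_minus."""
        ratio = abs(stdp_window(-d)) / stdp_window(d)
        assert ratio == pytest.approx(DEFAULTS.A_minus / DEFAULTS.A_plus)


class TestPairSum:
    def test_empty_train_contributes_nothing(self):
        assert pair_weight_change([], [1.0, 2.0]) == 0.0
        assert pair_weight_change([5.0], []) == 0.0

    def test_single_causal_pair(self):
        assert pair_weight_change([10.0], [15.0]) == pytest.approx(
            0.005 * math.exp(-0.25))

    def test_mixed_pairs(self):
        expected = 0.005 * math.exp(-0.25) - 0.00525 * math.exp(-0.75)
        assert pair_weight_change([10.0, 30.0], [15.0]) == pytest.approx(expected)
        assert expected == pytest.approx(0.0014141, abs=1e-7)

    def test_matches_bruteforce_on_random_trains(self, rng):
        for _ in range(100):
            pre = np.sort(rng.uniform(0, 50, rng.integers(0, 8)))
            post = np.sort(rng.uniform(0, 50, rng.integers(0, 8)))
            assert pair_weight_change(pre, post) == pytest.approx(
                brute_force_pair_sum(pre, post), abs=1e-12)

    @given(st.lists(st.floats(0, 50), max_size=6),
           st.lists(st.floats(0, 50), max_size=6),
           st.lists(st.floats(0, 50), min_size=1, max_size=6))
    def test_additive_over_disjoint_pre_sets(self, pre1, pre2, post):
        whole = pair_weight_change(pre1 + pre2, post)
        parts = pair_weight_change(pre1, post) + pair_weight_change(pre2, post)
        assert whole == pytest.approx(parts, abs=1e-12)


class TestSupervisedUpdate:
    def _toy(self, rng, n_pre=3, n_post=2):
        return SynapseMatrix(rng.uniform(0.3, 0.7, (n_pre, n_post)))

    def test_no_output_spikes_leaves_weights_unchanged(self, rng):
        syn = self._toy(rng)
        before = syn.weights.copy()
        supervised_update(syn, [[1.0], [2.0], [3.0]], [[], []], 0)
        np.testing.assert_array_equal(syn.weights, before)

    def test_matched_causal_pattern_potentiates(self, rng):
        syn = self._toy(rng)
        before = syn.weights.copy()
        supervised_update(syn, [[1.0], [2.0], [3.0]], [[6.0], []], 0)
        assert np.all(syn.weights[:, 0] > before[:, 0])
        np.testing.assert_array_equal(syn.weights[:, 1], before[:, 1])

    def test_mismatched_spiking_output_depresses(self, rng):
        syn = self._toy(rng)
        before = syn.weights.copy()
        supervised_update(syn, [[1.0], [2.0], [3.0]], [[], [6.0]], 0)
        np.testing.assert_array_equal(syn.weights[:, 0], before[:, 0])
        expected = before[:, 1] - np.array(
            [abs(brute_force_pair_sum([t], [6.0])) for t in (1.0, 2.0, 3.0)])
        np.testing.assert_allclose(syn.weights[:, 1], expected, rtol=1e-12)

    def test_label_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            supervised_update(self._toy(rng), [[1.0]] * 3, [[], []], 2)

    def test_weights_stay_clipped_after_many_updates(self, rng):
        syn = self._toy(rng)
        p = STDPParams(A_plus=0.5, A_minus=0.525)
        for _ in range(50):
            supervised_update(syn, [[0.0], [1.0], [2.0]], [[3.0], [3.0]], 0, p)
        assert syn.weights.min() >= p.w_min
        assert syn.weights.max() <= p.w_max

    def test_repeated_matched_presentations_saturate_upward(self, rng):
        """A fixed causal pattern drives the matched column monotonically to
        w_max."""
        syn = self._toy(rng)
        prev = syn.weights[:, 0].copy()
        for _ in range(400):
            supervised_update(syn, [[0.0], [0.5], [1.0]], [[2.0], []], 0)
            assert np.all(syn.weights[:, 0] >= prev - 1e-15)
            prev = syn.weights[:, 0].copy()
        np.testing.assert_allclose(prev, DEFAULTS.w_max)

    def test_mask_pins_unconnected_weights_at_zero(self, rng):
        mask = np.array([[True, False], [True, True], [False, True]])
        syn = SynapseMatrix(rng.uniform(0.3, 0.7, (3, 2)), mask=mask)
        supervised_update(syn, [[1.0], [2.0], [3.0]], [[6.0], [6.0]], 0)
        assert np.all(syn.weights[~mask] == 0.0)
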