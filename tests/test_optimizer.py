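"""The metaplastic update rule: attenuation function contract, branch logic,
reduction to plain Adam-BNN training at m=0, and flip statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metabnn.estimator import MetaplasticBNNClassifier
from metabnn.network import Network, binarize, mlp_spec
from metabnn.optimizer import (MetaplasticAdam, MetaplasticityConfig,
                               default_hard_threshold, f_meta, f_meta_hard_zero,
                               lr_decay_schedule)
from metabnn.tasks import SyntheticTaskSpec, generate_synthetic_tasks


class TestFMeta:
    def test_identity_at_m_zero(self, rng):
        x = rng.normal(scale=10, size=50)
        np.testing.assert_array_equal(f_meta(0.0, x), np.ones(50))

    def test_unity_and_flat_at_origin(self):
        for m in (0.1, 1.0, 5.0):
            assert f_meta(m, 0.0) == 1.0
            # symmetric difference quotient vanishes at w = 0
            h = 1e-7
            assert (f_meta(m, h) - f_meta(m, -h)) / (2 * h) == pytest.approx(0.0, abs=1e-6)

    def test_known_values(self):
        # sech^2 evaluated independently: 1/cosh(10)^2 and 1 - tanh(2)^2
        assert f_meta(1.0, 10.0) == pytest.approx(1.0 / math.cosh(10.0) ** 2, rel=1e-12)
        assert f_meta(1.0, 10.0) == pytest.approx(8.24e-9, rel=1e-3)
        assert f_meta(1.0, 2.0) == pytest.approx(0.07065, abs=1e-5)

    def test_negative_m_rejected(self):
        with pytest.raises(ValueError):
            f_meta(-0.1, 1.0)

    @settings(deadline=None, max_examples=200)
    @given(m=st.floats(0.0, 10.0), w=st.floats(-30.0, 30.0))
    def test_range_and_evenness(self, m, w):
        v = float(f_meta(m, w))
        assert 0.0 < v <= 1.0
        assert v == pytest.approx(float(f_meta(m, -w)), rel=1e-12)

    @settings(deadline=None, max_examples=100)
    @given(m=st.floats(0.01, 5.0), w=st.floats(0.0, 20.0), dw=st.floats(0.001, 5.0))
    def test_monotone_decay_in_magnitude(self, m, w, dw):
        assert f_meta(m, w + dw) <= f_meta(m, w)

    def test_decay_to_zero_at_infinity(self):
        assert f_meta(2.0, 1e3) < 1e-12


class TestHardZero:
    def test_zero_beyond_threshold_and_smooth_below(self):
        w = np.array([0.0, 0.5, 1.0, 1.5])
        out = f_meta_hard_zero(1.0, w, threshold=1.0)
        np.testing.assert_array_equal(out[2:], [0.0, 0.0])
        np.testing.assert_allclose(out[:2], f_meta(1.0, w[:2]))
        assert out[0] == 1.0

    def test_infinite_threshold_recovers_smooth(self, rng):
        w = rng.normal(scale=3, size=100)
        np.testing.assert_array_equal(f_meta_hard_zero(1.3, w, math.inf),
                                      f_meta(1.3, w))

    def test_missing_threshold_rejected(self):
        with pytest.raises(ValueError):
            f_meta_hard_zero(1.0, 0.5, None)

    def test_default_threshold_at_floor(self):
        thr = default_hard_threshold(1.35, floor=1e-3)
        assert f_meta(1.35, thr) == pytest.approx(1e-3, rel=1e-9)
        assert f_meta(1.35, 0.999 * thr) > 1e-3


class TestLrDecay:
    def test_schedule_values(self):
        assert lr_decay_schedule(0, 1e-3) == 1e-3
        assert lr_decay_schedule(2, 1e-3) == pytest.approx(1e-5)

    def test_strictly_decreasing(self):
        lrs = [lr_decay_schedule(k, 1e-3) for k in range(6)]
        assert all(a > b for a, b in zip(lrs, lrs[1:]))


class _IdentityAdam(MetaplasticAdam):
    """Optimizer whose composite update equals the raw gradient, isolating
    the metaplastic branch logic for exact hand-computed checks."""

    def _adam_update(self, g, m1, m2):
        return g.copy()


class TestBranchLogic:
    def _one_weight_net(self, hidden_value):
        net = Network(mlp_spec((1, 1), batch_norm=False), seed=0)
        net.dense_layers[0].hidden[...] = hidden_value
        return net

    def test_attenuated_branch_hand_value(self):
        # W^h = 2 (W^b = +1), update U = +0.1 opposes the sign: the new
        # hidden weight is 2 - 0.1 * sech^2(2) = 1.9929349...
        net = self._one_weight_net(2.0)
        opt = _IdentityAdam(net, m=1.0, lr=1.0)
        opt.step([np.array([[0.1]])], [])
        assert net.dense_layers[0].hidden[0, 0] == pytest.approx(
            2.0 - 0.1 * (1.0 - math.tanh(2.0) ** 2), rel=1e-12)
        assert net.dense_layers[0].hidden[0, 0] == pytest.approx(1.992935, abs=1e-6)

    def test_unattenuated_branch(self):
        for m in (0.0, 1.0, 5.0):
            net = self._one_weight_net(2.0)
            opt = _IdentityAdam(net, m=m, lr=1.0)
            opt.step([np.array([[-0.1]])], [])
            assert net.dense_layers[0].hidden[0, 0] == pytest.approx(2.1)

    def test_zero_update_is_noop(self):
        net = self._one_weight_net(-1.5)
        opt = _IdentityAdam(net, m=2.0, lr=1.0)
        opt.step([np.array([[0.0]])], [])
        assert net.dense_layers[0].hidden[0, 0] == -1.5

    def test_attenuation_never_reverses_direction(self, rng):
        net = Network(mlp_spec((4, 6, 2), batch_norm=False), seed=1)
        before = [h.copy() for h in net.hidden_weights()]
        grads = [rng.normal(size=h.shape) for h in before]
        opt = _IdentityAdam(net, m=1.35, lr=0.1)
        opt.step(grads, [])
        for b, a, g in zip(before, net.hidden_weights(), grads):
            delta = a - b
            raw = -0.1 * g
            moved = g != 0
            assert np.all(np.sign(delta[moved]) == np.sign(raw[moved]))
            assert np.all(np.abs(delta) <= np.abs(raw) + 1e-15)

    def test_sustained_opposition_eventually_flips(self):
        # smooth f_meta is strictly positive, so a constant opposing update
        # flips any finite hidden weight eventually
        net = self._one_weight_net(2.0)
        opt = _IdentityAdam(net, m=1.35, lr=1.0)
        for _ in range(10_000):
            opt.step([np.array([[0.05]])], [])
            if net.dense_layers[0].hidden[0, 0] < 0:
                break
        assert net.dense_layers[0].hidden[0, 0] < 0

    def test_hard_zero_makes_consolidation_definitive(self):
        net = self._one_weight_net(2.0)
        opt = _IdentityAdam(net, m=1.35, variant="hard_zero", hard_threshold=1.0, lr=1.0)
        for _ in range(1000):
            opt.step([np.array([[0.05]])], [])
        assert net.dense_layers[0].hidden[0, 0] == 2.0

    def test_shape_mismatch_rejected(self):
        net = self._one_weight_net(1.0)
        opt = _IdentityAdam(net, m=0.0)
        with pytest.raises(ValueError):
            opt.step([np.zeros((2, 2))], [])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MetaplasticityConfig(m=-1.0)
        with pytest.raises(ValueError):
            MetaplasticityConfig(m=1.0, variant="banana")


def _reference_adam_bnn(x, y, sizes, seed, steps, lr, batch):
    """Independently coded plain BNN trained with Adam: sign weights and
    activations, hard-tanh STE, softmax cross-entropy, no batch norm.

    Written from the standard construction, sharing no code with the
    package; returns the hidden-weight trajectory endpoint.
    """
    rng = np.random.default_rng(seed)
    Ws = [rng.uniform(-1 / np.sqrt(a), 1 / np.sqrt(a), size=(a, b))
          for a, b in zip(sizes, sizes[1:])]
    m1 = [np.zeros_like(w) for w in Ws]
    m2 = [np.zeros_like(w) for w in Ws]
    b1, b2, eps = 0.9, 0.999, 1e-8
    shuffle = np.random.default_rng(seed + 10_000)
    order = []
    t = 0
    while t < steps:
        perm = shuffle.permutation(len(y))
        for i in range(0, len(perm), batch):
            order.append(perm[i:i + batch])
            t += 1
            if t >= steps:
                break
    for t, idx in enumerate(order, start=1):
        xb, yb = x[idx], y[idx]
        Wb = [np.where(w >= 0, 1.0, -1.0) for w in Ws]
        # forward
        acts = [xb]
        pre = []
        h = xb
        for li, wb in enumerate(Wb):
            a = h @ wb
            pre.append(a)
            h = np.where(a >= 0, 1.0, -1.0) if li < len(Wb) - 1 else a
            acts.append(h)
        z = h - h.max(axis=1, keepdims=True)
        p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        d = p.copy()
        d[np.arange(len(yb)), yb] -= 1.0
        d /= len(yb)
        # backward
        grads = [None] * len(Ws)
        for li in range(len(Ws) - 1, -1, -1):
            grads[li] = acts[li].T @ d
            if li > 0:
                d = (d @ Wb[li].T) * (np.abs(pre[li - 1]) <= 1.0)
        # plain Adam on hidden weights
        for w, g, a1, a2 in zip(Ws, grads, m1, m2):
            a1 *= b1
            a1 += (1 - b1) * g
            a2 *= b2
            a2 += (1 - b2) * g * g
            u = (a1 / (1 - b1 ** t)) / (np.sqrt(a2 / (1 - b2 ** t)) + eps)
            w -= lr * u
    return Ws


class TestPlainBnnReduction:
    def test_m_zero_matches_independent_adam_bnn_100_steps(self, small_tasks):
        """At m=0 the metaplastic optimizer IS plain Adam-BNN training:
        100 steps on a fixed task match an independent implementation
        elementwise."""
        x, y = small_tasks[0].train
        sizes = (x.shape[1], 16, 4)
        steps, lr, batch = 100, 1e-3, 24  # 240 examples -> 10 steps/epoch
        clf = MetaplasticBNNClassifier(hidden_layer_sizes=sizes[1:-1], m=0.0,
                                       learning_rate=lr, batch_size=batch,
                                       batch_norm=False, random_state=11)
        clf.partial_fit(x, y, classes=np.unique(y), epochs=10)
        assert clf.optimizer_.t == steps
        ref = _reference_adam_bnn(x, y, sizes, seed=11, steps=steps,
                                  lr=lr, batch=batch)
        for mine, theirs in zip(clf.network_.hidden_weights(), ref):
            np.testing.assert_array_equal(mine, theirs)


class TestFlipStatistics:
    def test_task2_flip_fraction_decreases_with_m(self):
        """Across m in {0, 0.5, 1.0, 1.35}, the fraction of binary weights
        flipped while training a second task decreases (consolidation)."""
        spec = SyntheticTaskSpec(n_classes=4, n_features=24,
                                 n_train_per_class=60, n_test_per_class=10, seed=3)
        flips = []
        for m in (0.0, 0.5, 1.0, 1.35):
            tasks = generate_synthetic_tasks(spec, 2)
            clf = MetaplasticBNNClassifier(hidden_layer_sizes=(32,), m=m,
                                           learning_rate=2e-2, batch_size=16,
                                           random_state=5)
            x, y = tasks[0].train
            clf.partial_fit(x, y, classes=np.unique(y), bn_slot=0, epochs=15)
            before = [binarize(h) for h in clf.network_.hidden_weights()]
            x2, y2 = tasks[1].train
            clf.partial_fit(x2, y2, bn_slot=1, epochs=15)
            after = [binarize(h) for h in clf.network_.hidden_weights()]
            n = sum(b.size for b in before)
            flips.append(sum(np.sum(a != b) for a, b in zip(after, before)) / n)
        assert flips[0] > flips[-1]
        # allow small sampling inversions between neighbouring m values
        for a, b in zip(flips, flips[1:]):
            assert b <= a * 1.1
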