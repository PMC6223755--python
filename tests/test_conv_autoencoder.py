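"""Autoencoder stage: loss formulas, encode/decode contracts, brute-force
oracles, analytic gradients and greedy stacked training."""

import hashlib

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathae import ShapeError
from pathae.conv_autoencoder import (
    FeatureMap,
    StageConfig,
    TrainConfig,
    decode_stage,
    encode_stage,
    init_stage,
    reconstruction_loss,
    sparsity_entropy,
    stack_encode,
    total_loss,
    train_stack,
    train_stage,
)
from pathae.conv_autoencoder import _stage_loss_and_grads
from pathae.synthetic_data import tiny_fixture

from _oracles import conv_sigmoid_pool as _oracle_conv_sigmoid_pool
from _oracles import unpool_deconv as _oracle_unpool_deconv


class TestEncodeDecode:
    def test_encode_shape_contract(self):
        st_ = init_stage(5, 16, 3, seed=0)
        z = encode_stage(np.random.default_rng(0).uniform(0, 1, (64, 64, 3)), st_)
        assert z.shape == (32, 32, 16)
        assert z.values.min() > 0 and z.values.max() < 1

    def test_zero_weights_give_half(self, tiny_stage):
        st_ = init_stage(3, 2, 3, seed=0)
        st_.encode_filters[:] = 0
        st_.encode_bias[:] = 0
        z = encode_stage(np.zeros((8, 8, 3)), st_)
        assert np.allclose(z.values, 0.5)

    def test_odd_spatial_dims_rejected(self, tiny_stage):
        with pytest.raises(ShapeError):
            encode_stage(np.zeros((7, 8, 3)), tiny_stage)

    def test_encode_matches_nested_loop_oracle(self, tiny_stage):
        x, _ = tiny_fixture()
        got = encode_stage(x, tiny_stage).values
        want = _oracle_conv_sigmoid_pool(x, tiny_stage.encode_filters, tiny_stage.encode_bias)
        assert np.abs(got - want).max() < 1e-6

    def test_decode_shape_and_unpool_definition(self, tiny_stage):
        y = decode_stage(FeatureMap(np.full((4, 4, 2), 0.3)), tiny_stage)
        assert y.shape == (8, 8, 3)
        # unpool of a single value becomes a constant 2x2 block per channel
        from pathae._nn import unpool2

        u = unpool2(np.array([[[[0.7]]]]))
        assert np.array_equal(u[0, :, :, 0], np.array([[0.7, 0.7], [0.7, 0.7]]))

    def test_decode_matches_nested_loop_oracle(self, tiny_stage):
        z = np.random.default_rng(5).uniform(0, 1, (2, 2, 2))
        got = decode_stage(FeatureMap(z), tiny_stage)
        want = _oracle_unpool_deconv(z, tiny_stage.decode_filters, tiny_stage.decode_bias)
        assert np.abs(got - want).max() < 1e-6

    def test_roundtrip_preserves_shape(self):
        st_ = init_stage(4, 5, 3, seed=1)  # even filter size
        x = np.random.default_rng(1).uniform(0, 1, (10, 6, 3))
        assert decode_stage(encode_stage(x, st_), st_).shape == x.shape


class TestLosses:
    def test_reconstruction_identity_and_unit_gap(self):
        x, _ = tiny_fixture()
        assert reconstruction_loss(x, x) == 0.0
        assert reconstruction_loss(np.zeros((8, 8, 3)), np.ones((8, 8, 3))) == 192.0

    def test_reconstruction_shape_mismatch(self):
        with pytest.raises(ShapeError):
            reconstruction_loss(np.zeros((4, 4, 3)), np.zeros((4, 2, 3)))

    def test_entropy_closed_forms(self):
        uniform = np.ones((1, 1, 8))
        assert sparsity_entropy(uniform) == pytest.approx(np.log(8), abs=1e-12)
        onehot = np.zeros((1, 1, 8))
        onehot[0, 0, 3] = 2.0
        assert sparsity_entropy(onehot) == 0.0
        z = np.array([[[2.0, 1.0, 1.0]]])  # r = (1/2, 1/4, 1/4)
        want = -(0.5 * np.log(0.5) + 2 * 0.25 * np.log(0.25))
        assert sparsity_entropy(z) == pytest.approx(want, abs=1e-12)
        assert want == pytest.approx(1.0397, abs=1e-4)

    def test_entropy_zero_total_positions_contribute_zero(self):
        z = np.zeros((2, 2, 4))
        z[0, 0] = (1, 1, 1, 1)
        assert sparsity_entropy(z) == pytest.approx(np.log(4), abs=1e-12)

    def test_entropy_rejects_negative(self):
        with pytest.raises(ValueError):
            sparsity_entropy(np.array([[[-0.1, 0.5]]]))

    def test_total_loss_arithmetic(self):
        x = np.zeros((2, 2, 1))
        y = np.ones((2, 2, 1)) * np.sqrt(2.0 / 4)  # R = 4 * 0.5 = 2
        z = np.array([[[2.0, 1.0, 1.0]]])  # S = 1.0397
        lb = total_loss(x, y, z, 0.1)
        assert lb.R == pytest.approx(2.0)
        assert lb.L == pytest.approx(lb.R + 0.1 * lb.S, abs=1e-12)
        assert total_loss(x, y, z, 0.0).L == total_loss(x, y, z, 0.0).R
        assert lb.N == 4 and lb.M == 3

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 6), st.integers(1, 3))
    def test_entropy_bounds_property(self, seed, F, hw):
        """0 <= S <= (#positions) ln F for any nonnegative feature map."""
        z = np.random.default_rng(seed).uniform(0, 2, (hw, hw, F))
        s = sparsity_entropy(z)
        assert 0.0 <= s <= hw * hw * np.log(F) + 1e-9


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self, tiny_stage):
        """The full-stage backward pass agrees with central differences."""
        rng = np.random.default_rng(2)
        xb = rng.uniform(0, 1, (2, 8, 8, 3))
        L, _, _, grads = _stage_loss_and_grads(xb, tiny_stage, 0.05)
        eps = 1e-6
        for name, g in grads.items():
            arr = getattr(tiny_stage, name)
            for _ in range(3):
                idx = tuple(int(rng.integers(0, s)) for s in arr.shape)
                orig = arr[idx]
                arr[idx] = orig + eps
                up = _stage_loss_and_grads(xb, tiny_stage, 0.05)[0]
                arr[idx] = orig - eps
                dn = _stage_loss_and_grads(xb, tiny_stage, 0.05)[0]
                arr[idx] = orig
                assert (up - dn) / (2 * eps) == pytest.approx(g[idx], abs=1e-6)


def _hash(arr):
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


class TestTraining:
    def test_loss_decreases_and_deterministic(self, trained_small_stage, small_dataset):
        stage, history = trained_small_stage
        assert history[-1][0] < history[0][0]
        again, history2 = train_stage(
            small_dataset.train[0], StageConfig(5, 8),
            TrainConfig(learning_rate=3e-3, batch_size=8, steps=60, lambda_s=1e-3, seed=11),
        )
        assert history == history2
        assert np.array_equal(stage.encode_filters, again.encode_filters)

    def test_empty_data_rejected(self):
        from pathae import DataError

        with pytest.raises(DataError):
            train_stage([], StageConfig(3, 4), TrainConfig(steps=1, seed=0))

    def test_stack_shapes_freeze_and_composition(self, small_dataset):
        imgs = small_dataset.train[0][:8]
        cfgs = [StageConfig(5, 4), StageConfig(3, 6)]
        cfg = TrainConfig(learning_rate=3e-3, batch_size=4, steps=10, lambda_s=1e-3, seed=5)
        stages = train_stack(imgs, cfgs, cfg)
        # greedy schedule: stage 1 alone trains identically to stage 1 in the stack
        solo, _ = train_stage(imgs, cfgs[0], TrainConfig(
            learning_rate=3e-3, batch_size=4, steps=10, lambda_s=1e-3, seed=5))
        assert _hash(stages[0].encode_filters) == _hash(solo.encode_filters)
        assert _hash(stages[0].decode_filters) == _hash(solo.decode_filters)
        z = stack_encode(imgs[0], stages)
        assert z.shape == (8, 8, 6)
        nested = encode_stage(encode_stage(imgs[0], stages[0]), stages[1])
        assert np.abs(z.values - nested.values).max() < 1e-12

    def test_stack_empty_is_identity(self):
        x = np.random.default_rng(0).uniform(0, 1, (8, 8, 3))
        assert np.array_equal(stack_encode(x, []).values, x)

    def test_indivisible_dims_rejected(self, small_dataset):
        imgs = [im[:18, :18] for im in small_dataset.train[0][:4]]
        with pytest.raises(ShapeError):
            train_stack(imgs, [StageConfig(3, 2)] * 3,
                        TrainConfig(steps=1, batch_size=2, seed=0))
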