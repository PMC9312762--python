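"""Structure and contracts of the reconstruction network."""

import numpy as np
import pytest

from ssrnet.model import ModelConfig, SSRNet, sinusoidal_positions


@pytest.fixture(scope="module")
def tiny_model():
    return SSRNet(ModelConfig.tiny(inventory_size=7, seed=3))


def rand_input(n, rng_seed=0):
    return np.random.default_rng(rng_seed).standard_normal((n, 355))


class TestFftBlock:
    def test_shape_preserved(self, tiny_model):
        h = np.random.default_rng(0).standard_normal((12, 32))
        out = tiny_model.fft_block(h)
        assert out.shape == (12, 32)

    def test_masked_frames_do_not_leak(self, tiny_model):
        rng = np.random.default_rng(1)
        h1 = rng.standard_normal((10, 32))
        h2 = h1.copy()
        mask = np.ones(10, bool)
        mask[7:] = False
        h2[7:] = rng.standard_normal((3, 32))  # differ only on masked frames
        o1 = tiny_model.fft_block(h1, mask=mask).data
        o2 = tiny_model.fft_block(h2, mask=mask).data
        assert np.allclose(o1[:7], o2[:7], atol=1e-12)

    def test_deterministic(self, tiny_model):
        h = np.random.default_rng(2).standard_normal((8, 32))
        a = tiny_model.fft_block(h).data
        b = tiny_model.fft_block(h).data
        assert np.array_equal(a, b)

    def test_mask_length_mismatch(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.fft_block(np.zeros((5, 32)), mask=np.ones(4, bool))


class TestEncoder:
    def test_output_width_is_d_model(self, tiny_model):
        out = tiny_model.encode(rand_input(9))
        assert out.shape == (9, 32)

    def test_empty_sequence_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.encode(np.zeros((0, 355)))

    def test_wrong_dim_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.encode(np.zeros((4, 10)))

    def test_positional_encoding_breaks_permutation_invariance(self, tiny_model):
        X = rand_input(8, rng_seed=5)
        perm = np.random.default_rng(6).permutation(8)
        out = tiny_model.encode(X).data
        out_p = tiny_model.encode(X[perm]).data
        # with positions active, permuting frames is not just a row permutation
        assert not np.allclose(out[perm], out_p, atol=1e-6)

    def test_sinusoidal_table(self):
        pe = sinusoidal_positions(4, 6)
        assert pe.shape == (4, 6)
        assert np.allclose(pe[0, 0::2], 0.0) and np.allclose(pe[0, 1::2], 1.0)


class TestDurationPredictor:
    def test_length_and_nonnegativity(self, tiny_model):
        h = tiny_model.encode(rand_input(11))
        d = tiny_model.predict_durations(h)
        assert d.shape == (11,)
        assert np.all(d.data >= 0)

    def test_gradient_reaches_predictor(self, tiny_model):
        from ssrnet._autograd import Tensor

        h = tiny_model.encode(rand_input(6))
        d = tiny_model.predict_durations(h)
        loss = (d - Tensor(np.ones(6))).pow(2.0).mean()
        for p in tiny_model.parameters():
            p.grad = None
        loss.backward()
        assert any(
            p.grad is not None and np.any(p.grad != 0)
            for k, p in tiny_model.params.items()
            if k.startswith("dur.")
        )


class TestDecoder:
    def test_output_shapes(self, tiny_model):
        h = tiny_model.encode(rand_input(7))
        pre, post = tiny_model.decode(h)
        assert pre.shape == (7, 80) and post.shape == (7, 80)

    def test_zeroed_postnet_makes_residual_identity(self):
        m = SSRNet(ModelConfig.tiny(inventory_size=3, seed=1))
        for k, p in m.params.items():
            if k.startswith("post."):
                p.data = np.zeros_like(p.data)
        h = m.encode(rand_input(5))
        pre, post = m.decode(h)
        assert np.allclose(pre.data, post.data, atol=1e-14)


class TestJointHeads:
    def test_shapes_and_softmax(self, tiny_model):
        h = tiny_model.encode(rand_input(6))
        logits, recon = tiny_model.joint_heads(h)
        assert logits.shape == (6, 7)
        assert recon.shape == (6, 355)
        probs = logits.softmax_last().data
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_missing_inventory_rejected(self):
        m = SSRNet(ModelConfig.tiny(seed=0))
        h = m.encode(rand_input(3))
        with pytest.raises(ValueError):
            m.joint_heads(h)

    def test_head_position_switch_changes_input_layer(self):
        X = rand_input(6, rng_seed=8)
        d = np.ones(6, int)
        before = SSRNet(ModelConfig.tiny(inventory_size=4, seed=2))
        after = SSRNet(
            ModelConfig.tiny(inventory_size=4, seed=2, toneme_head_position="after_decoder")
        )
        # identical weights, different wiring
        for k in before.params:
            after.params[k].data = before.params[k].data.copy()
        ob = before.forward_train(X, d, training=False)
        oa = after.forward_train(X, d, training=False)
        # before-decoder head sees the regulated hidden states directly
        assert np.allclose(
            ob.toneme_logits.data,
            (ob.hidden_regulated @ before.params["toneme_head.W"]).data
            + before.params["toneme_head.b"].data,
        )
        assert not np.allclose(ob.toneme_logits.data, oa.toneme_logits.data)


class TestForward:
    def test_train_shapes(self, tiny_model):
        X = rand_input(10)
        d = np.ones(10, int)
        d[0] = 2
        d[3] = 0
        out = tiny_model.forward_train(X, d, training=False)
        M = int(d.sum())
        assert out.mel_pre.shape == (M, 80)
        assert out.mel_post.shape == (M, 80)
        assert out.toneme_logits.shape == (M, 7)
        assert out.emg_recon.shape == (M, 355)
        assert out.durations_pred.shape == (10,)

    def test_identity_regulation(self, tiny_model):
        X = rand_input(9)
        out = tiny_model.forward_train(X, np.ones(9, int), training=False)
        assert out.mel_post.shape == (9, 80)

    def test_unregulated_equals_all_ones_durations(self, tiny_model):
        X = rand_input(8, rng_seed=4)
        mel = tiny_model.forward_unregulated(X).frames
        out = tiny_model.forward_train(X, np.ones(8, int), training=False)
        assert np.allclose(mel, out.mel_post.data, atol=1e-12)

    def test_output_length_law(self, tiny_model):
        rng = np.random.default_rng(11)
        for _ in range(5):
            n = int(rng.integers(3, 15))
            d = rng.integers(0, 4, size=n)
            if d.sum() == 0:
                d[0] = 1
            out = tiny_model.forward_train(rand_input(n, rng_seed=int(rng.integers(1e6))), d, training=False)
            assert out.mel_post.shape[0] == int(d.sum())

    def test_infer_requires_training_flag(self):
        m = SSRNet(ModelConfig.tiny(inventory_size=3, seed=0))
        with pytest.raises(RuntimeError):
            m.forward_infer(rand_input(5))

    def test_infer_length_and_determinism(self, tiny_model):
        tiny_model.is_trained = True
        X = rand_input(12, rng_seed=9)
        d_int = tiny_model.infer_durations(X)
        mel1 = tiny_model.forward_infer(X).frames
        mel2 = tiny_model.forward_infer(X).frames
        assert mel1.shape[0] == int(d_int.sum()) >= 1
        assert np.array_equal(mel1, mel2)


class TestPersistence:
    def test_save_load_roundtrip_bitstable(self, tmp_path, tiny_model):
        tiny_model.is_trained = True
        X = rand_input(6, rng_seed=13)
        before = tiny_model.forward_infer(X).frames
        p = tmp_path / "ckpt.npz"
        tiny_model.normalization = {"emg_mean": np.zeros(355)}
        tiny_model.save(p)
        loaded = SSRNet.load(p)
        after = loaded.forward_infer(X).frames
        assert np.array_equal(before, after)
        assert np.array_equal(loaded.normalization["emg_mean"], np.zeros(355))

    def test_parameter_count_is_config_determined(self):
        a = SSRNet(ModelConfig.tiny(inventory_size=5, seed=0))
        b = SSRNet(ModelConfig.tiny(inventory_size=5, seed=99))
        assert a.parameter_count() == b.parameter_count() > 0
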