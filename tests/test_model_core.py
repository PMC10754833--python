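"""Generator/discriminator contracts: encodings, gate limits, residual
skips, softmax closed forms, and both losses against independent oracles."""

import math

import numpy as np
import pytest

from grud import nn
from grud.nn.autograd import Tensor
from grud.model_core import (Discriminator, Generator, GeneratorConfig,
                             discriminator_loss, generator_loss,
                             generator_softmax, maf_weights, one_hot_encode,
                             total_loss)


def reference_gru_cell(x_t, a_prev, Wz, Uz, bz, Wr, Ur, br, Wn, Un, bn):
    """From-scratch single GRU cell used as an oracle (update gate gates the
    candidate; reset gate gates the recurrent term of the candidate)."""
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))
    z = sig(x_t @ Wz + a_prev @ Uz + bz)
    r = sig(x_t @ Wr + a_prev @ Ur + br)
    n = np.tanh(x_t @ Wn + r * (a_prev @ Un) + bn)
    return z * n + (1.0 - z) * a_prev


def make_generator(rng, n_inputs=6, n_targets=4, **cfg_kwargs):
    defaults = dict(hidden_units=3, num_layers=2, feature_size=4)
    defaults.update(cfg_kwargs)
    cfg = GeneratorConfig(**defaults)
    input_pos = np.arange(1, n_inputs + 1) * 100
    target_pos = np.arange(1, n_targets + 1) * 100 + 50
    return Generator(input_pos, target_pos, cfg, rng), cfg


class TestOneHot:
    def test_definition(self):
        np.testing.assert_array_equal(
            one_hot_encode([0, 1, 1]), [[1, 0], [0, 1], [0, 1]])

    def test_empty(self):
        assert one_hot_encode(np.zeros((0,))).shape == (0, 2)

    def test_argmax_roundtrip(self, rng):
        x = (rng.random(50) < 0.5).astype(int)
        np.testing.assert_array_equal(one_hot_encode(x).argmax(axis=-1), x)

    def test_rejects_nonbinary(self):
        with pytest.raises(ValueError):
            one_hot_encode([0, 2])


class TestSequentialFeatures:
    def test_identity_configuration(self, rng):
        # identity-ish linear map, slope 1, batch norm bypassed via eval mode
        # with neutral running stats -> output equals the zero-padded input
        gen, cfg = make_generator(rng, feature_size=4)
        gen.feature_linear.weight.data[...] = 0.0
        gen.feature_linear.weight.data[0, 0] = 1.0
        gen.feature_linear.weight.data[1, 1] = 1.0
        gen.feature_linear.bias.data[...] = 0.0
        gen.config.leaky_slope = 1.0
        gen.eval()
        enc = one_hot_encode((rng.random((3, 6)) < 0.5).astype(int))
        out = gen.sequential_features(enc).data
        np.testing.assert_allclose(out[..., :2], enc / np.sqrt(1 + 1e-5), atol=1e-9)
        np.testing.assert_allclose(out[..., 2:], 0.0, atol=1e-12)

    def test_training_batch_statistics(self, rng):
        gen, cfg = make_generator(rng, n_inputs=8, feature_size=5)
        enc = one_hot_encode((rng.random((16, 8)) < 0.5).astype(int))
        # independent oracle: batch statistics of the pre-normalization
        # activations predict the output std as sqrt(var / (var + eps))
        w, b = gen.feature_linear.weight.data, gen.feature_linear.bias.data
        pre = enc.reshape(-1, 2) @ w + b
        pre = np.where(pre >= 0, pre, gen.config.leaky_slope * pre)
        expected_std = np.sqrt(pre.var(axis=0) / (pre.var(axis=0) + 1e-5))
        out = gen.sequential_features(enc).data.reshape(-1, 5)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-7)
        np.testing.assert_allclose(out.std(axis=0), expected_std, atol=1e-9)

    def test_eval_mode_deterministic(self, rng):
        gen, _ = make_generator(rng)
        enc = one_hot_encode((rng.random((4, 6)) < 0.5).astype(int))
        gen.sequential_features(enc)  # populate running stats
        gen.eval()
        a = gen.sequential_features(enc).data
        b = gen.sequential_features(enc).data
        np.testing.assert_array_equal(a, b)


class TestGruLimits:
    def test_zero_weights_gates_half(self, rng):
        x = rng.normal(size=(2, 3))
        a = rng.normal(size=(2, 4))
        zeros_w = np.zeros((3, 4))
        zeros_u = np.zeros((4, 4))
        sig = lambda v: 1.0 / (1.0 + np.exp(-v))
        gate = sig(x @ zeros_w + a @ zeros_u)
        np.testing.assert_array_equal(gate, np.full((2, 4), 0.5))
        # and the layer implementation agrees at zero weights
        gru = nn.GRULayer(3, 4, rng)
        gru.w_ih.data[...] = 0.0
        gru.w_hh.data[...] = 0.0
        gru.bias.data[...] = 0.0
        out = gru(Tensor(x[:, None, :])).data[:, 0, :]
        # z = r = 0.5, n = tanh(0), a0 = 0 -> output 0
        np.testing.assert_allclose(out, 0.0, atol=1e-15)

    def test_update_gate_zero_carries_state(self, rng):
        # forcing the update gate to 0 (via a large negative bias) must leave
        # the hidden state unchanged across timesteps
        gru = nn.GRULayer(3, 4, rng)
        H = 4
        gru.bias.data[:H] = -60.0  # z block: sigmoid(-60) == 0 in float64
        x = rng.normal(size=(2, 6, 3))
        out = gru(Tensor(x)).data
        np.testing.assert_allclose(out, 0.0, atol=1e-12)  # a stays at a_0 = 0

    def test_layer_matches_reference_cell(self, rng):
        gru = nn.GRULayer(3, 2, rng)
        H = 2
        W, U, b = gru.w_ih.data, gru.w_hh.data, gru.bias.data
        x = rng.normal(size=(1, 5, 3))
        a = np.zeros((1, H))
        for t in range(5):
            a = reference_gru_cell(
                x[:, t, :], a,
                W[:, :H], U[:, :H], b[:H],
                W[:, H:2 * H], U[:, H:2 * H], b[H:2 * H],
                W[:, 2 * H:], U[:, 2 * H:], b[2 * H:])
        np.testing.assert_allclose(gru(Tensor(x)).data[:, -1, :], a, atol=1e-12)


class TestBigruImpute:
    def test_skip_connection_identity_for_zero_layer(self, rng):
        # if a layer >1 computes the zero function, the skip leaves the
        # stack output unchanged
        gen, cfg = make_generator(rng, num_layers=2)
        enc = one_hot_encode((rng.random((3, 6)) < 0.5).astype(int))
        gen.eval()
        gen.sequential_features(enc)
        feats = gen.sequential_features(enc)
        full = gen.bigru_impute(feats).data
        for layer in (gen.gru_forward[1], gen.gru_backward[1]):
            layer.w_ih.data[...] = 0.0
            layer.w_hh.data[...] = 0.0
            layer.bias.data[...] = 0.0
        zeroed = gen.bigru_impute(gen.sequential_features(enc)).data
        # with layer 2 zeroed its output contributes nothing; the stack
        # reduces to layer 1's output passed through the read-out
        one_layer, _ = make_generator(rng, num_layers=1)
        for src, dst in [(gen.gru_forward[0], one_layer.gru_forward[0]),
                         (gen.gru_backward[0], one_layer.gru_backward[0])]:
            dst.w_ih.data[...] = src.w_ih.data
            dst.w_hh.data[...] = src.w_hh.data
            dst.bias.data[...] = src.bias.data
        one_layer.out_layer.weight.data[...] = gen.out_layer.weight.data
        one_layer.out_layer.bias.data[...] = gen.out_layer.bias.data
        np.testing.assert_allclose(
            zeroed, one_layer.bigru_impute(feats).data, atol=1e-12)

    @pytest.mark.parametrize("n_hap,n_inputs,n_targets,layers", [
        (2, 3, 1, 1), (5, 8, 11, 2), (3, 2, 6, 3)])
    def test_output_shape(self, rng, n_hap, n_inputs, n_targets, layers):
        gen, _ = make_generator(rng, n_inputs=n_inputs, n_targets=n_targets,
                                num_layers=layers)
        probs = gen.forward((rng.random((n_hap, n_inputs)) < 0.5).astype(int))
        assert probs.data.shape == (n_hap, n_targets, 2)

    def test_targets_outside_span_use_nearest_pair(self, rng):
        cfg = GeneratorConfig(hidden_units=2, num_layers=1, feature_size=3)
        gen = Generator([100, 200, 300], [50, 150, 350], cfg, rng)
        np.testing.assert_array_equal(gen.target_gaps, [0, 0, 1])

    def test_rejects_single_observed_site(self, rng):
        cfg = GeneratorConfig(hidden_units=2, num_layers=1, feature_size=3)
        with pytest.raises(ValueError):
            Generator([100], [150], cfg, rng)


class TestGeneratorSoftmax:
    def test_symmetric_logits(self):
        np.testing.assert_allclose(generator_softmax(np.zeros((1, 1, 2))),
                                   [[[0.5, 0.5]]])

    def test_closed_form(self):
        out = generator_softmax(np.array([[math.log(3.0), 0.0]]))
        np.testing.assert_allclose(out, [[0.75, 0.25]], atol=1e-12)

    def test_shift_invariance(self, rng):
        logits = rng.normal(size=(3, 4, 2))
        np.testing.assert_allclose(generator_softmax(logits),
                                   generator_softmax(logits + 7.3), atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        out = generator_softmax(rng.normal(size=(5, 6, 2)) * 30)
        np.testing.assert_allclose(out.sum(axis=-1), 1.0, atol=1e-6)


def bce_oracle(z, zh, eps=1e-7):
    """Independent plain BCE, elementwise mean."""
    zh = np.clip(zh, eps, 1 - eps)
    return float(np.mean(-(z * np.log(zh) + (1 - z) * np.log(1 - zh))))


class TestGeneratorLoss:
    def test_exact_prediction_near_zero(self):
        z = np.array([[0.0, 1.0, 1.0]])
        loss = generator_loss(z, z.copy(), np.full(3, 0.3), gamma=1.0)
        assert 0.0 <= loss <= 1e-6

    def test_unit_weight_closed_form(self):
        for gamma in (-1.0, 0.0, 2.5):
            loss = generator_loss(np.array([[1.0]]), np.array([[0.5]]),
                                  np.array([0.5]), gamma=gamma)
            np.testing.assert_allclose(loss, math.log(2.0), atol=1e-12)

    def test_gamma_zero_matches_plain_bce(self, rng):
        for _ in range(25):
            z = (rng.random((4, 6)) < 0.5).astype(float)
            zh = rng.uniform(0.01, 0.99, size=(4, 6))
            maf = rng.uniform(0.0, 0.5, size=6)
            np.testing.assert_allclose(generator_loss(z, zh, maf, 0.0),
                                       bce_oracle(z, zh), atol=1e-10)

    def test_weight_scaling_is_linear(self, rng):
        # doubling one site's weight doubles its loss contribution
        z = (rng.random((3, 4)) < 0.5).astype(float)
        zh = rng.uniform(0.1, 0.9, size=(3, 4))
        maf = np.array([0.05, 0.1, 0.2, 0.25])
        base = generator_loss(z, zh, maf, gamma=1.0)
        doubled_site = maf.copy()
        doubled_site[2] *= 2  # (2 maf)^1 doubles
        bumped = generator_loss(z, zh, doubled_site, gamma=1.0)
        site_bce = -np.mean(z[:, 2] * np.log(zh[:, 2])
                            + (1 - z[:, 2]) * np.log(1 - zh[:, 2]))
        expected_delta = (2 * maf[2]) * site_bce / 4  # weight added once / N
        np.testing.assert_allclose(bumped - base, expected_delta, atol=1e-10)

    def test_negative_gamma_zero_maf_rejected(self):
        with pytest.raises(ValueError):
            generator_loss(np.array([[1.0]]), np.array([[0.5]]),
                           np.array([0.0]), gamma=-1.0)
        # but a configured floor clips the weight instead
        loss = generator_loss(np.array([[1.0]]), np.array([[0.5]]),
                              np.array([0.0]), gamma=-1.0, maf_floor=0.005)
        np.testing.assert_allclose(loss, (2 * 0.005) ** -1.0 * math.log(2))

    def test_tensor_input_returns_tensor(self):
        t = Tensor(np.array([[0.7]]), requires_grad=True)
        loss = generator_loss(np.array([[1.0]]), t, np.array([0.5]))
        assert isinstance(loss, Tensor)
        loss.backward()
        assert t.grad is not None

    def test_maf_weights_validate_range(self):
        with pytest.raises(ValueError):
            maf_weights(np.array([0.7]), 1.0)


class TestDiscriminator:
    def test_zero_init_scores_half(self, rng):
        disc = Discriminator(5, rng)
        for layer in (disc.layer1, disc.layer2):
            layer.weight.data[...] = 0.0
            layer.bias.data[...] = 0.0
        scores = disc.forward(rng.random((7, 5))).data
        np.testing.assert_array_equal(scores, np.full(7, 0.5))

    def test_scores_are_probabilities(self, rng):
        disc = Discriminator(6, rng)
        scores = disc.forward(rng.random((10, 6)) * 5).data
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_real_and_fake_shapes_match(self, rng):
        disc = Discriminator(4, rng)
        real = (rng.random((3, 4)) < 0.5).astype(float)
        fake = rng.random((3, 4))
        assert disc.forward(real).shape == disc.forward(fake).shape == (3,)

    def test_length_mismatch_raises(self, rng):
        disc = Discriminator(4, rng)
        with pytest.raises(ValueError):
            disc.forward(rng.random((3, 5)))


class TestDiscriminatorLoss:
    def test_exact_prediction_near_zero(self):
        p = np.array([1.0, 0.0, 1.0])
        assert discriminator_loss(p, p.copy()) < 1e-6

    def test_closed_form(self):
        np.testing.assert_allclose(
            discriminator_loss(np.array([1.0]), np.array([0.5])),
            math.log(2.0), atol=1e-12)

    def test_matches_bce_oracle(self, rng):
        for _ in range(25):
            p = (rng.random(8) < 0.5).astype(float)
            ph = rng.uniform(0.01, 0.99, size=8)
            np.testing.assert_allclose(discriminator_loss(p, ph),
                                       bce_oracle(p, ph), atol=1e-10)


class TestLossValue:
    def test_total_is_exact_sum(self):
        from grud.model_core import LossValue
        lv = LossValue(l_g=0.3, l_d=0.2)
        assert lv.total == lv.l_d + lv.l_g


class TestTotalLoss:
    def test_addition(self):
        assert total_loss(0.3, 0.2) == pytest.approx(0.5)
        assert total_loss(0.0, 0.0) == 0.0

    def test_scaling_commutes(self):
        assert total_loss(2 * 0.3, 2 * 0.2) == pytest.approx(2 * total_loss(0.3, 0.2))

    def test_tensor_inputs(self):
        out = total_loss(Tensor(np.array(0.3)), Tensor(np.array(0.2)))
        assert isinstance(out, Tensor)
        np.testing.assert_allclose(out.data, 0.5)
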