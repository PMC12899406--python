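"""Architecture contracts: encoder shapes, attention pooling, gated fusion,
classifier head and the parameter budget."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amwfnet import nn
from amwfnet.network import (AmwfnetModel, AttentionPool, AttentionPoolConfig,
                             EncoderConfig, GateConfig, GatedFusion,
                             HeadConfig, ModelConfig, architecture_fingerprint,
                             count_parameters, make_image_encoder)


class TestEncoder:
    def test_feature_matrix_shape(self):
        model = AmwfnetModel(seed=0)
        model.eval()
        x = np.random.default_rng(0).random((1, 11, 32, 32)).astype(np.float32)
        F = model._encode(model.encoder_emg, x[:, :8])
        assert F.shape == (1, 8, 128)

    def test_identical_planes_identical_rows(self):
        model = AmwfnetModel(seed=0)
        model.eval()
        plane = np.random.default_rng(1).random((1, 1, 32, 32)).astype(np.float32)
        planes = np.repeat(plane, 8, axis=1)
        F = model._encode(model.encoder_emg, planes)
        assert np.allclose(F[0, 0], F[0, 7], atol=1e-5)

    def test_wrong_spatial_size_rejected(self):
        model = AmwfnetModel(seed=0)
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 11, 24, 24), dtype=np.float32), np.array([1]))

    def test_spatial_footprint_before_gap(self):
        """Four 2x2 pools reduce 128 -> 8 per side."""
        enc = make_image_encoder(EncoderConfig(), np.random.default_rng(0))
        enc.eval()
        x = np.random.default_rng(2).random((1, 128, 128, 1)).astype(np.float32)
        h = x
        for layer in enc.layers[:-1]:
            h = layer.forward(h)
        assert h.shape == (1, 8, 8, 128)


class TestAttentionPool:
    def test_uniform_for_identical_rows(self):
        pool = AttentionPool(AttentionPoolConfig(), np.random.default_rng(0))
        F = np.repeat(np.random.default_rng(1).random((2, 1, 128)), 5, axis=1)
        pooled, alpha = pool.forward(F.astype(np.float32))
        assert np.allclose(alpha, 0.2, atol=1e-6)
        assert np.allclose(pooled, F[:, 0], atol=1e-5)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(1, 11), st.integers(0, 2**31 - 1))
    def test_softmax_contract(self, n_planes, seed):
        pool = AttentionPool(AttentionPoolConfig(), np.random.default_rng(0))
        F = np.random.default_rng(seed).standard_normal(
            (3, n_planes, 128)).astype(np.float32)
        pooled, alpha = pool.forward(F)
        assert np.all(alpha > 0)
        assert np.allclose(alpha.sum(axis=1), 1.0, atol=1e-6)
        # pooled vector stays inside the convex hull's coordinate bounds
        assert np.all(pooled <= F.max(axis=1) + 1e-5)
        assert np.all(pooled >= F.min(axis=1) - 1e-5)

    def test_single_channel(self):
        pool = AttentionPool(AttentionPoolConfig(), np.random.default_rng(0))
        F = np.random.default_rng(3).standard_normal((3, 1, 128)).astype(np.float32)
        pooled, alpha = pool.forward(F)
        assert np.allclose(alpha, 1.0)
        assert np.allclose(pooled, F[:, 0])

    def test_permutation_equivariance(self):
        pool = AttentionPool(AttentionPoolConfig(), np.random.default_rng(0))
        F = np.random.default_rng(4).standard_normal((2, 8, 128)).astype(np.float32)
        pooled, alpha = pool.forward(F)
        perm = np.random.default_rng(5).permutation(8)
        pooled_p, alpha_p = pool.forward(F[:, perm])
        assert np.allclose(alpha_p, alpha[:, perm], atol=1e-6)
        assert np.allclose(pooled_p, pooled, atol=1e-5)


class TestGatedFusion:
    def _gate_with_logits(self, l_emg, l_kine, tau):
        gate = GatedFusion(GateConfig(tau=tau), np.random.default_rng(0))
        final = gate.mlp.layers[-1]
        final.weight.value[...] = 0.0
        final.bias.value[...] = [l_emg, l_kine]
        return gate

    def test_equal_logits_half_half(self):
        for tau in (0.5, 2.5, 10.0):
            gate = self._gate_with_logits(1.7, 1.7, tau)
            rng = np.random.default_rng(1)
            fe = rng.standard_normal((3, 128)).astype(np.float32)
            fk = rng.standard_normal((3, 128)).astype(np.float32)
            fused, w = gate.forward(fe, fk)
            assert np.allclose(w, 0.5, atol=1e-6)
            assert np.allclose(fused, 0.5 * fe + 0.5 * fk, atol=1e-5)

    def test_hand_evaluated_softmax(self):
        gate = self._gate_with_logits(2.0, 0.0, 2.5)
        fe = np.zeros((1, 128), dtype=np.float32)
        fk = np.zeros((1, 128), dtype=np.float32)
        _, w = gate.forward(fe, fk)
        expected = np.exp(0.8) / (np.exp(0.8) + 1.0)
        assert w[0, 0] == pytest.approx(expected, rel=1e-5)

    def test_temperature_limits(self):
        near_uniform = self._gate_with_logits(2.0, 0.0, 1e4)
        _, w = near_uniform.forward(np.zeros((1, 128), np.float32),
                                    np.zeros((1, 128), np.float32))
        assert np.allclose(w, 0.5, atol=1e-3)
        winner = self._gate_with_logits(2.0, 0.0, 1e-2)
        _, w = winner.forward(np.zeros((1, 128), np.float32),
                              np.zeros((1, 128), np.float32))
        assert w[0, 0] > 0.999

    def test_gate_monotone_in_logit_gap(self):
        gaps = np.linspace(-3, 3, 7)
        ws = []
        for gap in gaps:
            g = self._gate_with_logits(gap, 0.0, 2.5)
            _, w = g.forward(np.zeros((1, 128), np.float32),
                             np.zeros((1, 128), np.float32))
            ws.append(w[0, 0])
        assert np.all(np.diff(ws) > 0)

    def test_entropy_nondecreasing_in_tau(self):
        def entropy(w):
            return float(-(w * np.log(w)).sum())
        es = []
        for tau in (0.5, 1.0, 2.5, 5.0, 10.0):
            g = self._gate_with_logits(2.0, 0.0, tau)
            _, w = g.forward(np.zeros((1, 128), np.float32),
                             np.zeros((1, 128), np.float32))
            es.append(entropy(w[0]))
        assert np.all(np.diff(es) >= -1e-12)

    def test_fusion_convexity(self):
        gate = GatedFusion(GateConfig(), np.random.default_rng(0))
        rng = np.random.default_rng(2)
        fe = rng.standard_normal((5, 128)).astype(np.float32)
        fk = rng.standard_normal((5, 128)).astype(np.float32)
        fused, w = gate.forward(fe, fk)
        assert np.allclose(w.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(w > 0)
        recon = w[:, :1] * fe + w[:, 1:] * fk
        assert np.allclose(fused, recon, atol=1e-6)
        norms = np.linalg.norm(fused, axis=1)
        bound = np.maximum(np.linalg.norm(fe, axis=1), np.linalg.norm(fk, axis=1))
        assert np.all(norms <= bound + 1e-4)

    def test_invalid_temperature_rejected(self):
        with pytest.raises(ValueError):
            GateConfig(tau=0.0)


class TestModel:
    def test_logit_shape_and_composite_width(self):
        model = AmwfnetModel(seed=0)
        model.eval()
        x = np.random.default_rng(0).random((2, 11, 16, 16)).astype(np.float32)
        logits = model.forward(x, np.array([1, 18]))
        assert logits.shape == (2, 6)
        assert model.head.layers[0].weight.value.shape == (128, 146)

    def test_invalid_action_rejected(self):
        model = AmwfnetModel(seed=0)
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 11, 16, 16), np.float32), np.array([0]))
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 11, 16, 16), np.float32), np.array([19]))

    def test_eval_mode_deterministic(self):
        model = AmwfnetModel(seed=0)
        model.eval()
        x = np.random.default_rng(1).random((2, 11, 16, 16)).astype(np.float32)
        a = model.forward(x, np.array([3, 4]))
        b = model.forward(x, np.array([3, 4]))
        assert np.array_equal(a, b)

    def test_model_gradients_finite_difference(self):
        cfg = ModelConfig(
            encoder=EncoderConfig(channel_sequence=(1, 2, 2, 3, 3), feature_dim=3),
            attention=AttentionPoolConfig(feature_dim=3, hidden_dim=2),
            gate=GateConfig(feature_dim=3, hidden_dim=4),
            head=HeadConfig(feature_dim=3, dropout=0.0))
        model = AmwfnetModel(cfg, seed=1)
        model.train(True)
        rng = np.random.default_rng(0)
        x = rng.random((3, 11, 16, 16)).astype(np.float32)
        acts = np.array([1, 7, 18])
        y = np.array([0, 3, 5])

        def loss():
            return nn.softmax_cross_entropy(model.forward(x, acts), y)

        _, d = loss()
        model.zero_grad()
        model.backward(d)
        params = model.parameters()
        check_rng = np.random.default_rng(2)
        for p_idx in check_rng.choice(len(params), size=10, replace=False):
            par = params[p_idx]
            flat = par.value.reshape(-1)
            i = int(check_rng.integers(flat.size))
            eps, old = 1e-2, flat[i]
            flat[i] = old + eps
            l1, _ = loss()
            flat[i] = old - eps
            l2, _ = loss()
            flat[i] = old
            num = (l1 - l2) / (2 * eps)
            ana = float(par.grad.reshape(-1)[i])
            assert abs(num - ana) <= 0.1 * max(0.05, abs(num) + abs(ana))


class TestParameterBudget:
    def test_exact_counts(self):
        model = AmwfnetModel(seed=0)
        assert count_parameters(model) == 1_268_554
        enc = make_image_encoder(EncoderConfig(), np.random.default_rng(0))
        assert sum(p.value.size for p in enc.parameters()) == 583_008

    def test_count_stable_across_seeds(self):
        assert count_parameters(AmwfnetModel(seed=1)) == \
            count_parameters(AmwfnetModel(seed=99))

    def test_fingerprint(self):
        model = AmwfnetModel(seed=0)
        fp = architecture_fingerprint(model)
        assert fp["total_parameters"] == 1_268_554
        assert fp["head"][0] == [128, 146]
        assert fp["head"][-1] == [6]
        assert fp["config"]["tau"] == 2.5

    def test_variant_configs(self):
        semg = AmwfnetModel(ModelConfig(use_kine=False), seed=0)
        assert not hasattr(semg, "encoder_kine")
        kine = AmwfnetModel(ModelConfig(use_emg=False), seed=0)
        assert not hasattr(kine, "encoder_emg")
        noact = AmwfnetModel(ModelConfig(use_action=False), seed=0)
        assert noact.head.layers[0].weight.value.shape == (128, 128)
        concat = AmwfnetModel(ModelConfig(fusion="concat"), seed=0)
        assert not hasattr(concat, "gate")
        assert concat.concat_reduce.weight.value.shape == (128, 256)
        with pytest.raises(ValueError):
            ModelConfig(use_emg=False, use_kine=False)
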