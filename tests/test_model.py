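import math

import numpy as np
import pytest

from eegemo.autodiff import Tensor, parameter
from eegemo.model import (
    ModelConfig,
    ModelError,
    attention_weights,
    bgru,
    classify,
    forward,
    forward_batch,
    global_encode,
    gru_step,
    init_params,
    iter_parameters,
    load_checkpoint,
    make_attention,
    make_gru_layer,
    n_parameters,
    regional_encode,
    save_checkpoint,
    self_attention,
    stream_encode_2bgrua,
)
from eegemo.montage import REGION_IDS

from conftest import random_encoder_inputs


def zero_gru_direction(d_in, d_h):
    return {
        f"{w}{g}": parameter(np.zeros((d_in if w == "W" else d_h, d_h)))
        for g in "zrh"
        for w in "WU"
    } | {f"b{g}": parameter(np.zeros(d_h)) for g in "zrh"}


def gru_step_oracle(x, h, p):
    """Hand-coded per-element GRU update (independent of the Tensor engine)."""
    sig = lambda v: 1.0 / (1.0 + math.exp(-v))
    d_h = h.size
    out = np.zeros(d_h)
    for j in range(d_h):
        z = sig(x @ p["Wz"].data[:, j] + h @ p["Uz"].data[:, j] + p["bz"].data[j])
        r_row = np.array(
            [
                sig(x @ p["Wr"].data[:, k] + h @ p["Ur"].data[:, k] + p["br"].data[k])
                for k in range(d_h)
            ]
        )
        cand = math.tanh(
            x @ p["Wh"].data[:, j] + (r_row * h) @ p["Uh"].data[:, j] + p["bh"].data[j]
        )
        out[j] = (1 - z) * h[j] + z * cand
    return out


class TestGruStep:
    def test_zero_network_maps_to_zero(self):
        p = zero_gru_direction(3, 4)
        h = gru_step(Tensor(np.ones(3)), Tensor(np.zeros(4)), p)
        assert np.array_equal(h.data, np.zeros(4))

    def test_saturated_update_gate_returns_candidate(self):
        rng = np.random.default_rng(0)
        p = {
            f"{w}{g}": parameter(rng.normal(size=(3 if w == "W" else 4, 4)) * 0.3)
            for g in "zrh"
            for w in "WU"
        } | {f"b{g}": parameter(np.zeros(4)) for g in "zrh"}
        p["bz"] = parameter(np.full(4, 50.0))  # update gate saturates at 1
        x = rng.normal(size=3)
        h_prev = rng.normal(size=4) * 0.5
        h = gru_step(Tensor(x), Tensor(h_prev), p).data
        # closed form with z = 1: h = tanh(x Wh + (r*h_prev) Uh)
        r = 1 / (1 + np.exp(-(x @ p["Wr"].data + h_prev @ p["Ur"].data)))
        cand = np.tanh(x @ p["Wh"].data + (r * h_prev) @ p["Uh"].data)
        assert np.allclose(h, cand, atol=1e-10)

    def test_matches_hand_coded_oracle_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            d_in, d_h = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            p = {
                f"{w}{g}": parameter(
                    rng.normal(size=(d_in if w == "W" else d_h, d_h))
                )
                for g in "zrh"
                for w in "WU"
            } | {f"b{g}": parameter(rng.normal(size=d_h)) for g in "zrh"}
            x = rng.normal(size=d_in)
            h_prev = rng.normal(size=d_h)
            ours = gru_step(Tensor(x), Tensor(h_prev), p).data
            assert np.allclose(ours, gru_step_oracle(x, h_prev, p), atol=1e-10)

    def test_state_stays_within_unit_bound_from_zero_init(self):
        rng = np.random.default_rng(2)
        p = {
            f"{w}{g}": parameter(rng.normal(size=(3 if w == "W" else 4, 4)))
            for g in "zrh"
            for w in "WU"
        } | {f"b{g}": parameter(rng.normal(size=4)) for g in "zrh"}
        h = Tensor(np.zeros(4))
        for t in range(50):
            h = gru_step(Tensor(rng.normal(size=3) * 10), h, p)
            # convex mixing of the previous state with a tanh candidate can
            # touch +-1 only through float saturation, never exceed it
            assert np.all(np.abs(h.data) <= 1.0)

    def test_dimension_mismatch_raises(self):
        p = zero_gru_direction(3, 4)
        with pytest.raises(ModelError, match="input dim"):
            gru_step(Tensor(np.zeros(5)), Tensor(np.zeros(4)), p)


class TestBgru:
    def test_output_is_concat_of_directions(self):
        rng = np.random.default_rng(0)
        layer = make_gru_layer(rng, 3, 4)
        seq = Tensor(rng.normal(size=(5, 3)))
        out = bgru(seq, layer).data
        assert out.shape == (5, 8)
        # forward half at t=0 equals a single forward step from zero state
        h0 = gru_step(seq[0, :], Tensor(np.zeros(4)), layer["fwd"]).data
        assert np.allclose(out[0, :4], h0, atol=1e-12)

    def test_length_one_sequence(self):
        rng = np.random.default_rng(1)
        layer = make_gru_layer(rng, 3, 4)
        x = rng.normal(size=(1, 3))
        out = bgru(Tensor(x), layer).data
        f = gru_step(Tensor(x[0]), Tensor(np.zeros(4)), layer["fwd"]).data
        b = gru_step(Tensor(x[0]), Tensor(np.zeros(4)), layer["bwd"]).data
        assert np.allclose(out[0], np.concatenate([f, b]), atol=1e-12)

    def test_zero_parameters_give_zero_outputs(self):
        layer = {
            "fwd": zero_gru_direction(3, 4),
            "bwd": zero_gru_direction(3, 4),
            "hidden": 4,
        }
        out = bgru(Tensor(np.random.default_rng(2).normal(size=(6, 3))), layer)
        assert np.array_equal(out.data, np.zeros((6, 8)))

    def test_time_reversal_with_swapped_directions(self):
        """Reversing the input and swapping forward/backward parameter sets
        reverses the output sequence and swaps its halves."""
        rng = np.random.default_rng(3)
        layer = make_gru_layer(rng, 3, 4)
        swapped = {"fwd": layer["bwd"], "bwd": layer["fwd"], "hidden": 4}
        x = rng.normal(size=(7, 3))
        out = bgru(Tensor(x), layer).data
        out_rev = bgru(Tensor(x[::-1].copy()), swapped).data
        recombined = np.concatenate([out_rev[::-1, 4:], out_rev[::-1, :4]], axis=1)
        assert np.allclose(out, recombined, atol=1e-12)

    def test_empty_sequence_raises(self):
        rng = np.random.default_rng(4)
        layer = make_gru_layer(rng, 3, 4)
        with pytest.raises(ModelError, match="non-empty"):
            bgru(Tensor(np.zeros((0, 3))), layer)


def attention_oracle(x, wq, wk, wv):
    """Double-loop softmax attention, independent of the Tensor engine."""
    q, k, v = x @ wq, x @ wk, x @ wv
    n, dk = k.shape
    out = np.zeros_like(v)
    for i in range(n):
        scores = np.array([q[i] @ k[j] / math.sqrt(dk) for j in range(n)])
        e = np.exp(scores - scores.max())
        w = e / e.sum()
        for j in range(n):
            out[i] += w[j] * v[j]
    return out


class TestSelfAttention:
    def test_single_row_returns_its_value_projection(self):
        rng = np.random.default_rng(0)
        attn = make_attention(rng, 4)
        x = rng.normal(size=(1, 4))
        out = self_attention(Tensor(x), attn).data
        assert np.allclose(out, x @ attn["W_V"].data, atol=1e-12)

    def test_zero_query_weights_give_uniform_mixture(self):
        rng = np.random.default_rng(1)
        attn = make_attention(rng, 4)
        attn["W_Q"] = parameter(np.zeros((4, 4)))
        x = rng.normal(size=(5, 4))
        out = self_attention(Tensor(x), attn).data
        v = x @ attn["W_V"].data
        assert np.allclose(out, np.tile(v.mean(axis=0), (5, 1)), atol=1e-12)

    def test_matches_double_loop_oracle_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n, d = int(rng.integers(1, 7)), int(rng.integers(1, 9))
            x = rng.normal(size=(n, d))
            attn = make_attention(rng, d)
            ours = self_attention(Tensor(x), attn).data
            oracle = attention_oracle(
                x, attn["W_Q"].data, attn["W_K"].data, attn["W_V"].data
            )
            assert np.allclose(ours, oracle, atol=1e-10)

    def test_attention_matrix_is_row_stochastic(self):
        rng = np.random.default_rng(3)
        attn = make_attention(rng, 6)
        w = attention_weights(rng.normal(size=(8, 6)) * 5, attn)
        assert np.all(w >= 0)
        assert np.allclose(w.sum(axis=-1), 1.0, atol=1e-12)

    def test_dimension_mismatch_raises(self):
        rng = np.random.default_rng(4)
        attn = make_attention(rng, 4)
        with pytest.raises(ModelError, match="model dim"):
            self_attention(Tensor(np.zeros((3, 5))), attn)


def classify_oracle(g, w, b):
    """Exp-normalise with python-scalar arithmetic (shift-stabilised)."""
    logits = g @ w + b
    m = max(logits)
    e = [math.exp(v - m) for v in logits]
    s = sum(e)
    return np.array([v / s for v in e])


class TestClassify:
    def test_zero_classifier_gives_uniform_probabilities(self):
        g = Tensor(np.random.default_rng(0).normal(size=8))
        p = classify(g, parameter(np.zeros((8, 4))), parameter(np.zeros(4))).data
        assert np.allclose(p, 0.25, atol=1e-12)

    def test_dominant_bias_wins(self):
        g = Tensor(np.zeros(8))
        b = parameter(np.array([0.0, 10.0, 0.0]))
        p = classify(g, parameter(np.zeros((8, 3))), b).data
        assert np.argmax(p) == 1
        assert p[1] > 0.9999

    def test_matches_exp_normalise_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            d, c = int(rng.integers(1, 9)), int(rng.integers(2, 6))
            g = rng.normal(size=d) * 10
            w, b = rng.normal(size=(d, c)), rng.normal(size=c)
            ours = classify(Tensor(g), parameter(w), parameter(b)).data
            assert np.allclose(ours, classify_oracle(g, w, b), atol=1e-10)
            assert abs(ours.sum() - 1.0) < 1e-12

    def test_argmax_tie_breaks_to_lowest_index(self):
        probs = np.array([0.4, 0.4, 0.2])
        assert int(np.argmax(probs)) == 0


TINY = dict(d=4, d_hc=3, d_hs=3, d_gc=3, d_gs=3, d_g=3, c=2)


class TestComposition:
    def test_stream_output_length_independent_of_sequence_length(self):
        rng = np.random.default_rng(0)
        from eegemo.model import _stream

        stream = _stream(rng, 4, 3, 3)
        for n in (1, 3, 5):
            out = stream_encode_2bgrua(Tensor(rng.normal(size=(n, 4))), stream)
            assert out.shape == (6,)

    def test_regional_vector_concatenates_spatial_then_temporal(self):
        cfg = ModelConfig(**TINY, seed=0)
        params = init_params(cfg)
        region = params["regions"]["R1"]
        rng = np.random.default_rng(1)
        H_r = Tensor(rng.normal(size=(4, 4)))  # N_r=4 positions, d=4
        U_r = Tensor(rng.normal(size=(5, 4)))
        L_r = regional_encode(H_r, U_r, region).data
        assert L_r.shape == (cfg.region_vector_dim,)
        s = stream_encode_2bgrua(H_r, region["spatial"]).data
        t = stream_encode_2bgrua(U_r, region["temporal"]).data
        assert np.allclose(L_r, np.concatenate([s, t]), atol=1e-12)

    def test_perturbing_time_sequence_leaves_spatial_half_unchanged(self):
        cfg = ModelConfig(**TINY, seed=0)
        params = init_params(cfg)
        region = params["regions"]["R1"]
        rng = np.random.default_rng(2)
        H_r = Tensor(rng.normal(size=(4, 4)))
        U_r = rng.normal(size=(5, 4))
        U_perturbed = U_r.copy()
        U_perturbed[2, 1] += 1.0
        L1 = regional_encode(H_r, Tensor(U_r), region).data
        L2 = regional_encode(H_r, Tensor(U_perturbed), region).data
        half = 2 * cfg.d_gc
        assert np.array_equal(L1[:half], L2[:half])
        assert not np.allclose(L1[half:], L2[half:])

    def test_global_encoder_rejects_wrong_token_count(self):
        cfg = ModelConfig(**TINY, seed=0)
        params = init_params(cfg)
        vecs = [Tensor(np.zeros(cfg.region_vector_dim)) for _ in range(8)]
        with pytest.raises(ModelError, match="9 region vectors"):
            global_encode(vecs, params["global"])

    def test_global_hidden_sequence_has_nine_tokens(self):
        cfg = ModelConfig(**TINY, seed=0)
        params = init_params(cfg)
        rng = np.random.default_rng(3)
        tokens = Tensor(rng.normal(size=(9, cfg.region_vector_dim)))
        e = bgru(tokens, params["global"]["bgru"])
        assert e.shape == (9, 2 * cfg.d_g)

    def test_forward_uniform_probabilities_with_zero_classifier(self, region_sizes):
        cfg = ModelConfig(**TINY, seed=0)
        params = init_params(cfg)
        params["classifier"]["W_z"].data[:] = 0
        params["classifier"]["b_z"].data[:] = 0
        rng = np.random.default_rng(4)
        H, U = random_encoder_inputs(rng, region_sizes, batch=2)
        probs = forward_batch(H, U, params).data
        assert np.allclose(probs, 0.5, atol=1e-12)

    def test_forward_deterministic_and_on_simplex(self, region_sizes):
        cfg = ModelConfig(**TINY, seed=1)
        params = init_params(cfg)
        rng = np.random.default_rng(5)
        H, U = random_encoder_inputs(rng, region_sizes, batch=3)
        p1 = forward_batch(H, U, params).data
        p2 = forward_batch(H, U, params).data
        assert np.array_equal(p1, p2)
        assert np.all(p1 >= 0)
        assert np.allclose(p1.sum(axis=-1), 1.0, atol=1e-12)

    @pytest.mark.parametrize("T", [1, 4])
    def test_forward_succeeds_for_any_sequence_lengths(self, region_sizes, T):
        from eegemo.features import EncoderInputs

        cfg = ModelConfig(**TINY, seed=2)
        params = init_params(cfg)
        rng = np.random.default_rng(6)
        H, U = random_encoder_inputs(rng, region_sizes, T=T)
        probs, cls = forward(EncoderInputs(H=H, U=U), params)
        assert probs.shape == (2,)
        assert cls in (0, 1)

    def test_missing_region_raises(self, region_sizes):
        from eegemo.features import EncoderInputs

        cfg = ModelConfig(**TINY, seed=2)
        params = init_params(cfg)
        rng = np.random.default_rng(7)
        H, U = random_encoder_inputs(rng, region_sizes)
        del H["R5"]
        with pytest.raises(ModelError, match="R5"):
            forward(EncoderInputs(H=H, U=U), params)


class TestGradients:
    def test_autodiff_matches_central_finite_differences(self, region_sizes):
        """End-to-end loss gradients on a tiny config agree with central
        finite differences at randomly chosen parameters to < 1e-4 relative."""
        from eegemo.train_eval import loss

        cfg = ModelConfig(**TINY, seed=3, lambda_reg=1e-3)
        params = init_params(cfg)
        rng = np.random.default_rng(8)
        H, U = random_encoder_inputs(rng, region_sizes, batch=3)
        labels = np.array([0, 1, 0])

        def compute():
            return loss(forward_batch(H, U, params), labels, params, cfg.lambda_reg)

        out = compute()
        out.backward()
        leaves = iter_parameters(params)
        max_rel = 0.0
        for _ in range(25):
            p = leaves[int(rng.integers(len(leaves)))]
            idx = tuple(int(rng.integers(s)) for s in p.data.shape)
            eps = 1e-6
            old = p.data[idx]
            p.data[idx] = old + eps
            fp = compute().data
            p.data[idx] = old - eps
            fm = compute().data
            p.data[idx] = old
            fd = (fp - fm) / (2 * eps)
            ad = p.grad[idx]
            rel = abs(fd - ad) / max(abs(fd), abs(ad), 1e-8)
            max_rel = max(max_rel, rel)
        assert max_rel < 1e-4


class TestParamsAndCheckpoint:
    def test_parameter_tree_shapes_follow_config(self):
        cfg = ModelConfig(d=4, d_hc=5, d_hs=6, d_gc=7, d_gs=8, d_g=9, c=3, seed=0)
        params = init_params(cfg)
        r1 = params["regions"]["R1"]
        assert r1["spatial"]["layer1"]["fwd"]["Wz"].shape == (4, 5)
        assert r1["spatial"]["layer2"]["fwd"]["Wz"].shape == (10, 7)
        assert r1["temporal"]["layer2"]["fwd"]["Wz"].shape == (12, 8)
        assert r1["spatial"]["attention"]["W_Q"].shape == (14, 14)
        assert params["global"]["bgru"]["fwd"]["Wz"].shape == (2 * 7 + 2 * 8, 9)
        assert params["classifier"]["W_z"].shape == (18, 3)

    def test_shared_region_mode_shrinks_parameter_count(self):
        per_region = init_params(ModelConfig(**TINY, seed=0))
        shared = init_params(ModelConfig(**TINY, seed=0, shared_regions=True))
        assert n_parameters(shared) < n_parameters(per_region)

    def test_same_seed_reproduces_initialisation(self):
        a = init_params(ModelConfig(**TINY, seed=5))
        b = init_params(ModelConfig(**TINY, seed=5))
        for pa, pb in zip(iter_parameters(a), iter_parameters(b)):
            assert np.array_equal(pa.data, pb.data)

    def test_checkpoint_roundtrip_bit_exact(self, tmp_path):
        cfg = ModelConfig(**TINY, seed=6)
        params = init_params(cfg)
        for p in iter_parameters(params):
            p.data += np.random.default_rng(0).normal(size=p.data.shape)
        path = tmp_path / "model.npz"
        save_checkpoint(path, params, cfg)
        loaded, loaded_cfg = load_checkpoint(path)
        assert loaded_cfg == cfg
        for pa, pb in zip(iter_parameters(params), iter_parameters(loaded)):
            assert np.array_equal(pa.data, pb.data)
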