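import numpy as np
import pytest

from molcycle import LATENT_DIM
from molcycle.networks import (
    AttentionParams,
    DiscriminatorParams,
    GeneratorParams,
    LSTMParams,
    attention_pool,
    discriminator_forward,
    generator_forward,
    init_attention,
    init_discriminator,
    init_generator,
    init_lstm,
    load_params,
    lstm_step,
    save_params,
    sigmoid,
)


def oracle_lstm_step(x_t, h_prev, c_prev, p):
    """Independent straight-from-the-gate-equations implementation."""
    hx = np.concatenate([h_prev, np.atleast_1d(x_t)])
    f = 1 / (1 + np.exp(-(p.W_f @ hx + p.b_f)))
    i = 1 / (1 + np.exp(-(p.W_i @ hx + p.b_i)))
    C_bar = np.tanh(p.W_C @ hx + p.b_C)
    c = f * c_prev + i * C_bar
    o = 1 / (1 + np.exp(-(p.W_o @ hx + p.b_o)))
    return o * np.tanh(c), c


def oracle_attention(seq, p):
    """Independent scaled-dot-product attention with final-element query."""
    seq = np.asarray(seq, dtype=float)
    q = seq[-1] @ p.query_proj
    scores = np.array([(seq[t] @ p.key_proj) @ q for t in range(len(seq))])
    scores = scores / np.sqrt(p.key_width)
    e = np.exp(scores - scores.max())
    w = e / e.sum()
    vals = np.array([(seq[t] @ p.value_proj)[0] for t in range(len(seq))])
    return float(w @ vals), w


def zero_lstm(hidden, input_width):
    cols = hidden + input_width
    z = lambda *s: np.zeros(s)
    return LSTMParams(
        W_f=z(hidden, cols), W_i=z(hidden, cols), W_C=z(hidden, cols),
        W_o=z(hidden, cols), b_f=z(hidden), b_i=z(hidden), b_C=z(hidden),
        b_o=z(hidden),
    )


class TestLSTMStep:
    def test_zero_parameters(self):
        p = zero_lstm(4, 2)
        h, c = lstm_step(np.ones(2), np.zeros(4), np.zeros(4), p)
        # gates sit at sigmoid(0)=0.5, candidate tanh(0)=0 -> everything stays 0
        np.testing.assert_allclose(c, 0.0)
        np.testing.assert_allclose(h, 0.0)

    def test_saturated_forget_gate_preserves_cell(self):
        p = zero_lstm(3, 1)
        p.b_f[:] = 100.0  # forget gate ~ 1
        c_prev = np.array([0.7, -0.2, 1.5])
        _, c = lstm_step(np.zeros(1), np.zeros(3), c_prev, p)
        np.testing.assert_allclose(c, c_prev, atol=1e-10)

    def test_hidden_bounded(self, rng):
        p = init_lstm(rng, 8, 3)
        for _ in range(20):
            h, _ = lstm_step(
                rng.standard_normal(3) * 10,
                rng.standard_normal(8),
                rng.standard_normal(8) * 5,
                p,
            )
            assert np.all(np.abs(h) < 1.0)

    def test_against_oracle_100_draws(self, rng):
        for _ in range(100):
            hidden = int(rng.integers(1, 10))
            width = int(rng.integers(1, 6))
            p = init_lstm(rng, hidden, width)
            for arr in (p.W_f, p.W_i, p.W_C, p.W_o):
                arr += rng.standard_normal(arr.shape)
            for b in (p.b_f, p.b_i, p.b_C, p.b_o):
                b += rng.standard_normal(b.shape)
            x = rng.standard_normal(width)
            h0 = rng.standard_normal(hidden)
            c0 = rng.standard_normal(hidden)
            h, c = lstm_step(x, h0, c0, p)
            h_ref, c_ref = oracle_lstm_step(x, h0, c0, p)
            np.testing.assert_allclose(h, h_ref, rtol=1e-10)
            np.testing.assert_allclose(c, c_ref, rtol=1e-10)

    def test_shape_mismatch(self, rng):
        p = init_lstm(rng, 4, 2)
        with pytest.raises(ValueError):
            lstm_step(np.zeros(3), np.zeros(4), np.zeros(4), p)


class TestAttentionPool:
    def test_singleton_sequence(self, rng):
        p = init_attention(rng, 5)
        elem = rng.standard_normal(5)
        ctx, w = attention_pool([elem], p)
        np.testing.assert_allclose(w, [1.0])
        np.testing.assert_allclose(ctx, elem @ p.value_proj)

    def test_identical_elements_uniform_weights(self, rng):
        p = init_attention(rng, 4)
        elem = rng.standard_normal(4)
        ctx, w = attention_pool([elem, elem], p)
        np.testing.assert_allclose(w, [0.5, 0.5])
        np.testing.assert_allclose(ctx, elem @ p.value_proj)

    def test_hand_softmax_example(self):
        # scores (1, 0) before the 1/sqrt(64) scaling -> softmax(0.125, 0)
        q = np.zeros((2, 64)); q[0, 0] = 1.0
        k = np.zeros((2, 64)); k[1, 0] = 1.0
        v = np.zeros((2, 1))
        p = AttentionParams(query_proj=q, key_proj=k, value_proj=v)
        seq = np.array([[5.0, 1.0], [1.0, 0.0]])
        _, w = attention_pool(seq, p)
        np.testing.assert_allclose(w, [0.5312, 0.4688], atol=5e-5)

    def test_weights_sum_to_one(self, rng):
        p = init_attention(rng, 6)
        seq = rng.standard_normal((9, 6))
        _, w = attention_pool(seq, p)
        assert np.all(w >= 0)
        assert w.sum() == pytest.approx(1.0)

    def test_score_shift_invariance(self, rng):
        # a component that keys project but the query ignores shifts every
        # score by the same constant; softmax weights must not move
        q = np.zeros((3, 64)); q[:2] = rng.standard_normal((2, 64))
        k = np.zeros((3, 64)); k[:2] = rng.standard_normal((2, 64)); k[2, 0] = 1.0
        v = rng.standard_normal((3, 1))
        p = AttentionParams(query_proj=q, key_proj=k, value_proj=v)
        base = rng.standard_normal((5, 3)); base[:, 2] = 0.0
        shifted = base.copy(); shifted[:, 2] = 4.2
        # make the query see the same thing in both cases
        _, w1 = attention_pool(base, p)
        _, w2 = attention_pool(shifted, p)
        if (base[-1] @ q != shifted[-1] @ q).any():  # pragma: no cover
            pytest.skip("query changed")
        np.testing.assert_allclose(w1, w2, atol=1e-12)

    def test_against_oracle(self, rng):
        for _ in range(50):
            width = int(rng.integers(1, 8))
            length = int(rng.integers(1, 12))
            p = init_attention(rng, width)
            seq = rng.standard_normal((length, width))
            ctx, w = attention_pool(seq, p)
            ctx_ref, w_ref = oracle_attention(seq, p)
            np.testing.assert_allclose(w, w_ref, rtol=1e-10)
            np.testing.assert_allclose(ctx[0], ctx_ref, rtol=1e-9, atol=1e-12)

    def test_empty_rejected(self, rng):
        p = init_attention(rng, 3)
        with pytest.raises(ValueError):
            attention_pool(np.empty((0, 3)), p)


class TestGeneratorForward:
    def test_widths(self, rng):
        p = init_generator(rng)
        out, internals = generator_forward(
            rng.standard_normal(LATENT_DIM), p, return_internals=True
        )
        assert out.shape == (LATENT_DIM,)
        assert internals["fusion_width"] == 57
        assert internals["head_width"] == 56
        assert internals["tail_width"] == 1
        assert internals["output_width"] == 56

    def test_deterministic_inference(self, rng):
        p = init_generator(rng)
        z = rng.standard_normal(LATENT_DIM)
        np.testing.assert_array_equal(
            generator_forward(z, p), generator_forward(z, p)
        )

    def test_zero_parameters_give_fusion_bias(self, rng):
        p = init_generator(rng)
        for name, val in vars(p).items():
            if isinstance(val, np.ndarray):
                val[:] = 0.0
        for lstm in (p.lstm1, p.lstm2, p.lstm3):
            for arr in vars(lstm).values():
                arr[:] = 0.0
        for arr in (p.attention.query_proj, p.attention.key_proj, p.attention.value_proj):
            arr[:] = 0.0
        p.bn.gamma[:] = 0.0
        p.bn.beta[:] = 0.0
        bias = np.arange(LATENT_DIM, dtype=float)
        p.fusion_b = bias
        out = generator_forward(np.ones(LATENT_DIM) * 3.7, p, training=False)
        np.testing.assert_allclose(out, bias, atol=1e-12)

    def test_batch_matches_per_sample(self, rng):
        p = init_generator(rng)
        Z = rng.standard_normal((4, LATENT_DIM))
        batch = generator_forward(Z, p)
        single = np.stack([generator_forward(z, p) for z in Z])
        np.testing.assert_allclose(batch, single, rtol=1e-12)

    def test_wrong_width_rejected(self, rng):
        p = init_generator(rng)
        with pytest.raises(ValueError):
            generator_forward(np.zeros(55), p)

    def test_finite_numerical_gradient(self, rng):
        p = init_generator(rng)
        z = rng.standard_normal(LATENT_DIM)
        eps = 1e-6
        for idx in (0, 17, 55):
            zp = z.copy(); zp[idx] += eps
            zm = z.copy(); zm[idx] -= eps
            grad = (generator_forward(zp, p) - generator_forward(zm, p)) / (2 * eps)
            assert np.all(np.isfinite(grad))


class TestDiscriminatorForward:
    def test_scalar_output(self, rng):
        p = init_discriminator(rng)
        s = discriminator_forward(rng.standard_normal(LATENT_DIM), p)
        assert isinstance(s, float)
        assert np.isfinite(s)

    def test_zero_parameters_score_is_bias(self, rng):
        p = init_discriminator(rng)
        for arr in (p.dense1_W, p.dense1_b, p.dense2_W, p.dense2_b,
                    p.dense3_W, p.dense3_b, p.out_W,
                    p.attention.query_proj, p.attention.key_proj,
                    p.attention.value_proj):
            arr[:] = 0.0
        p.out_b = np.array([0.25])
        assert discriminator_forward(np.ones(LATENT_DIM), p) == pytest.approx(0.25)

    def test_sigmoid_bound_pre_output(self, rng):
        # with the printed sigmoid enabled, score is an affine map of (0,1)
        p = init_discriminator(rng, final_sigmoid=True)
        w, b = float(p.out_W[0, 0]), float(p.out_b[0])
        lo, hi = sorted((b, w + b))
        for _ in range(10):
            s = discriminator_forward(rng.standard_normal(LATENT_DIM) * 3, p)
            assert lo < s < hi

    def test_sigmoid_switch(self, rng):
        p_on = init_discriminator(rng, final_sigmoid=True)
        p_off = DiscriminatorParams(
            **{k: (v.copy() if isinstance(v, np.ndarray) else v)
               for k, v in vars(p_on).items() if k not in ("attention", "final_sigmoid")},
            attention=p_on.attention,
            final_sigmoid=False,
        )
        z = rng.standard_normal(LATENT_DIM)
        assert discriminator_forward(z, p_on) != discriminator_forward(z, p_off)

    def test_batch_matches_per_sample(self, rng):
        p = init_discriminator(rng)
        Z = rng.standard_normal((5, LATENT_DIM))
        batch = discriminator_forward(Z, p)
        single = np.array([discriminator_forward(z, p) for z in Z])
        np.testing.assert_allclose(batch, single, rtol=1e-12)


class TestParameterArchive:
    def test_roundtrip(self, rng, tmp_path):
        g = init_generator(rng)
        d = init_discriminator(rng)
        z = rng.standard_normal(LATENT_DIM)
        out_before = generator_forward(z, g)
        score_before = discriminator_forward(z, d)
        save_params(str(tmp_path / "arc"), {"G": g, "D": d}, seed=7)

        g2 = init_generator(np.random.default_rng(999))
        d2 = init_discriminator(np.random.default_rng(999))
        load_params(str(tmp_path / "arc"), {"G": g2, "D": d2})
        np.testing.assert_allclose(generator_forward(z, g2), out_before, rtol=1e-12)
        assert discriminator_forward(z, d2) == pytest.approx(score_before, rel=1e-12)

    def test_shape_mismatch_fails_loudly(self, rng, tmp_path):
        g = init_generator(rng)
        save_params(str(tmp_path / "arc"), {"G": g})
        d = init_discriminator(rng)
        with pytest.raises((ValueError, KeyError)):
            load_params(str(tmp_path / "arc"), {"G": d})
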