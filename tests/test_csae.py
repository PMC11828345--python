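"""CSAE attention: pooled descriptors, softmax attention, closed forms, and
equivalence with an independently coded naive-loop implementation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mae.attention import (
    CSAE,
    channel_attention,
    csae_forward,
    identity_filter,
    pool_descriptors,
    spatial_attention,
)
from mae.nn import Tensor

# ---------------------------------------------------------------------------
# Naive oracle: explicit loops, no shared code with the implementation.


def naive_csae(f: np.ndarray, filt_c: np.ndarray, filt_s: np.ndarray) -> np.ndarray:
    c, h, w = f.shape

    def conv_soft(vec, filt):
        k = len(filt)
        p = k // 2
        padded = [vec[0]] * p + list(vec) + [vec[-1]] * p  # edge replication
        raw = [sum(filt[j] * padded[i + j] for j in range(k)) for i in range(len(vec))]
        m = max(raw)
        e = [np.exp(r - m) for r in raw]
        z = sum(e)
        return [v / z for v in e]

    c_avg = [float(np.mean(f[k])) for k in range(c)]
    c_max = [float(np.max(f[:, i, j])) for i in range(h) for j in range(w)]
    wc = conv_soft(c_avg, list(filt_c))
    ws = conv_soft(c_max, list(filt_s))
    out = np.empty_like(f, dtype=float)
    for k in range(c):
        for i in range(h):
            for j in range(w):
                out[k, i, j] = wc[k] * f[k, i, j] + ws[i * w + j] * f[k, i, j]
    return out


# ---------------------------------------------------------------------------


class TestPoolDescriptors:
    def test_constant_map(self):
        d = pool_descriptors(np.full((3, 2, 4), 5.0))
        assert np.allclose(d.c_avg, 5.0) and d.c_avg.shape == (3,)
        assert np.allclose(d.c_max, 5.0) and d.c_max.shape == (8,)

    def test_two_channel_hand_case(self):
        f = np.stack([np.zeros((2, 2)), np.ones((2, 2))])
        d = pool_descriptors(f)
        assert np.allclose(d.c_avg, [0.0, 1.0])
        assert np.allclose(d.c_max, 1.0)

    def test_single_pixel(self):
        f = np.array([1.0, 2.0, 7.0]).reshape(3, 1, 1)
        d = pool_descriptors(f)
        assert np.allclose(d.c_avg, [1, 2, 7])
        assert np.allclose(d.c_max, [7])

    def test_rejects_nonfinite(self):
        f = np.zeros((2, 2, 2))
        f[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            pool_descriptors(f)


class TestAttentionVectors:
    def test_constant_descriptor_gives_uniform(self):
        d = pool_descriptors(np.full((5, 3, 3), 2.0))
        assert np.allclose(channel_attention(d, identity_filter(3)), 1 / 5)
        assert np.allclose(spatial_attention(d, identity_filter(3)), 1 / 9)

    def test_channel_closed_form(self):
        d = pool_descriptors(np.zeros((4, 1, 1)))
        d = type(d)(c_avg=np.array([0, 0, 0, np.log(3.0)]), c_max=d.c_max)
        w = channel_attention(d, identity_filter(3))
        assert np.allclose(w, [1 / 6, 1 / 6, 1 / 6, 1 / 2])

    def test_spatial_closed_form(self):
        d = pool_descriptors(np.zeros((1, 2, 2)))
        d = type(d)(c_avg=d.c_avg, c_max=np.array([0, 0, np.log(2.0), 0]))
        w = spatial_attention(d, identity_filter(3))
        assert np.allclose(w, [0.2, 0.2, 0.4, 0.2])

    def test_singleton_softmax(self):
        d = pool_descriptors(np.full((3, 1, 1), 1.0))
        assert np.allclose(spatial_attention(d, identity_filter(1)), [1.0])

    def test_even_kernel_rejected(self):
        d = pool_descriptors(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError):
            channel_attention(d, np.ones(2))

    def test_shift_invariance_of_attention(self, rng):
        # softmax(x + c) = softmax(x); with the delta filter the conv passes
        # the constant shift straight through.
        d = pool_descriptors(rng.normal(size=(4, 3, 3)))
        base = channel_attention(d, identity_filter(3))
        shifted = type(d)(c_avg=d.c_avg + 10.0, c_max=d.c_max)
        assert np.allclose(channel_attention(shifted, identity_filter(3)), base)


class TestCsaeForward:
    def test_constant_closed_form(self, rng):
        # constant value v in, v * (1/C + 1/(H*W)) out — for any filters.
        c, h, w = 4, 3, 5
        f = np.full((c, h, w), 7.0)
        expected = 7.0 * (1 / c + 1 / (h * w))
        for filt in (identity_filter(3), rng.normal(size=5)):
            out = csae_forward(f, filt_c=filt, filt_s=filt)
            assert np.allclose(out, expected)

    def test_zero_in_zero_out(self):
        assert np.allclose(csae_forward(np.zeros((2, 4, 4))), 0.0)

    def test_matches_naive_oracle_on_random_maps(self, rng):
        for _ in range(50):
            c = int(rng.integers(1, 6))
            h = int(rng.integers(1, 5))
            w = int(rng.integers(1, 5))
            f = rng.normal(size=(c, h, w))
            filt_c = rng.normal(size=3)
            filt_s = rng.normal(size=3)
            ours = csae_forward(f, filt_c=filt_c, filt_s=filt_s)
            assert np.allclose(ours, naive_csae(f, filt_c, filt_s), atol=1e-6)

    def test_frozen_attention_scaling(self, rng):
        f = rng.normal(size=(3, 4, 4))
        d = pool_descriptors(f)
        wc = channel_attention(d, identity_filter(3))
        ws = spatial_attention(d, identity_filter(3))

        def apply_frozen(g):
            return g * wc[:, None, None] + g * ws.reshape(1, 4, 4)

        assert np.allclose(apply_frozen(2.5 * f), 2.5 * apply_frozen(f))

    @given(
        c=st.integers(1, 6), h=st.integers(1, 6), w=st.integers(1, 6), seed=st.integers(0, 10**6)
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_shape_preservation_and_simplex(self, c, h, w, seed):
        f = np.random.default_rng(seed).normal(size=(c, h, w))
        out = csae_forward(f)
        assert out.shape == f.shape
        d = pool_descriptors(f)
        for vec in (channel_attention(d, identity_filter(3)), spatial_attention(d, identity_filter(3))):
            assert np.all(vec > 0)
            assert np.isclose(vec.sum(), 1.0, atol=1e-6)


class TestCsaeModule:
    def test_batched_module_matches_functional(self, rng):
        m = CSAE(kernel=3)
        m.filt_c.data = rng.normal(size=3)
        m.filt_s.data = rng.normal(size=3)
        x = rng.normal(size=(2, 3, 4, 4))
        out = m(Tensor(x)).data
        for i in range(2):
            ref = csae_forward(x[i], filt_c=m.filt_c.data, filt_s=m.filt_s.data)
            assert np.allclose(out[i], ref, atol=1e-10)

    def test_parameter_count_is_two_kernels(self):
        assert CSAE(kernel=3).num_parameters() == 6
        assert CSAE(kernel=5).num_parameters() == 10

    def test_gradients_flow_to_filters(self, rng):
        m = CSAE(kernel=3)
        x = Tensor(rng.normal(size=(1, 3, 4, 4)), requires_grad=True)
        (m(x) * m(x)).sum().backward()
        assert m.filt_c.grad is not None and np.any(m.filt_c.grad != 0)
        assert m.filt_s.grad is not None and np.any(m.filt_s.grad != 0)
        assert x.grad is not None

    def test_rescale_restores_magnitude(self):
        x = np.full((1, 4, 2, 2), 3.0)
        out = CSAE(kernel=3, rescale_attention=True)(Tensor(x)).data
        assert np.allclose(out, 6.0)  # 3 * (w_c*C + w_s*HW) = 3 * 2

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            CSAE(kernel=4)
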