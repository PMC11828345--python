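"""Channel-and-spatial attention enhancement (CSAE).

Given a backbone feature map ``f`` of shape C x H x W, two descriptor vectors
are pooled:

* ``c_avg`` (length C)  — spatial average of each channel slice;
* ``c_max`` (length H*W) — channel-wise maximum at each spatial position.

Each descriptor passes through a learnable single-filter, bias-free,
length-preserving (edge-padded) 1-D convolution followed by a softmax,
producing simplex attention
vectors ``w_c`` (channels) and ``w_s`` (positions).  The enhanced map is

    out[k, p] = w_c[k] * f[k, p]  +  w_s[p] * f[k, p]

so the module reweights the same features along both axes and sums the two
views.  Because each softmax sums to one, output magnitude shrinks as C and
H*W grow; ``rescale_attention=True`` multiplies ``w_c`` by C and ``w_s`` by
H*W to restore unit mean attention (off by default).

The module adds exactly ``2 * kernel`` trainable parameters.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from mae.nn.autograd import Tensor
from mae.nn.layers import Module, Parameter, conv1d_same

__all__ = [
    "ChannelDescriptor",
    "pool_descriptors",
    "channel_attention",
    "spatial_attention",
    "csae_forward",
    "CSAE",
    "identity_filter",
]


@dataclasses.dataclass(frozen=True)
class ChannelDescriptor:
    """Pooled views of a feature map: c_avg over space, c_max over channels."""

    c_avg: np.ndarray  # (C,)
    c_max: np.ndarray  # (H*W,)


def _check_finite(f: np.ndarray) -> None:
    if not np.all(np.isfinite(f)):
        raise ValueError("feature map contains non-finite values")


def pool_descriptors(f: np.ndarray) -> ChannelDescriptor:
    """Average-pool each channel and max-pool across channels.

    ``f`` is a C x H x W array; returns c_avg of length C and c_max of length
    H*W (row-major flattening of the spatial grid).
    """
    f = np.asarray(f, dtype=float)
    if f.ndim != 3:
        raise ValueError(f"expected CxHxW feature map, got shape {f.shape}")
    _check_finite(f)
    return ChannelDescriptor(c_avg=f.mean(axis=(1, 2)), c_max=f.max(axis=0).ravel())


def identity_filter(kernel: int) -> np.ndarray:
    """The delta filter: 1-D convolution with it is the identity map."""
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"kernel size must be odd and >= 1, got {kernel}")
    w = np.zeros(kernel)
    w[kernel // 2] = 1.0
    return w


def _conv1d_np(x: np.ndarray, filt: np.ndarray) -> np.ndarray:
    """Edge-padded same-length 1-D cross-correlation (single filter, no bias).

    Edge-replicate padding maps constant descriptors to constant outputs for
    every filter, so constant feature maps always receive uniform attention.
    """
    k = filt.shape[0]
    if k % 2 == 0:
        raise ValueError(f"kernel size must be odd, got {k}")
    p = k // 2
    xp = np.pad(x, p, mode="edge")
    return np.array([xp[i : i + k] @ filt for i in range(x.shape[0])])


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max())
    return e / e.sum()


def channel_attention(d: ChannelDescriptor, filt: np.ndarray) -> np.ndarray:
    """Channel attention: softmax(conv1d(c_avg, filt)); a length-C simplex vector."""
    return _softmax(_conv1d_np(np.asarray(d.c_avg, dtype=float), np.asarray(filt, dtype=float)))


def spatial_attention(d: ChannelDescriptor, filt: np.ndarray) -> np.ndarray:
    """Spatial attention: softmax(conv1d(c_max, filt)); a length-(H*W) simplex vector."""
    return _softmax(_conv1d_np(np.asarray(d.c_max, dtype=float), np.asarray(filt, dtype=float)))


def csae_forward(
    f: np.ndarray,
    filt_c: np.ndarray | None = None,
    filt_s: np.ndarray | None = None,
    kernel: int = 3,
    rescale_attention: bool = False,
) -> np.ndarray:
    """Functional CSAE on a single C x H x W map (no gradients).

    With ``filt_c``/``filt_s`` omitted, identity filters of size ``kernel``
    are used.  Shape is preserved.
    """
    f = np.asarray(f, dtype=float)
    if f.ndim != 3:
        raise ValueError(f"expected CxHxW feature map, got shape {f.shape}")
    _check_finite(f)
    if filt_c is None:
        filt_c = identity_filter(kernel)
    if filt_s is None:
        filt_s = identity_filter(kernel)
    c, h, w = f.shape
    d = pool_descriptors(f)
    w_c = channel_attention(d, filt_c)
    w_s = spatial_attention(d, filt_s)
    if rescale_attention:
        w_c = w_c * c
        w_s = w_s * (h * w)
    return f * w_c[:, None, None] + f * w_s.reshape(1, h, w)


class CSAE(Module):
    """Trainable CSAE operating on batched feature maps (N, C, H, W).

    The two 1-D filters are initialized to the identity (delta) filter so the
    module starts as plain softmax attention over the raw descriptors and
    learns deviations from there.
    """

    def __init__(self, kernel: int = 3, rescale_attention: bool = False):
        if kernel < 1 or kernel % 2 == 0:
            raise ValueError(f"kernel size must be odd and >= 1, got {kernel}")
        self.kernel = kernel
        self.rescale_attention = rescale_attention
        self.filt_c = Parameter(identity_filter(kernel))
        self.filt_s = Parameter(identity_filter(kernel))

    def attention(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Return (w_c, w_s) simplex tensors of shapes (N, C) and (N, H*W)."""
        n, c, h, w = x.data.shape
        hw = h * w
        c_avg = x.sum(axis=3).sum(axis=2) * (1.0 / hw)  # (N, C)
        c_max = x.max(axis=1).reshape(n, hw)  # (N, H*W)
        w_c = conv1d_same(c_avg, self.filt_c, pad_mode="edge").softmax(axis=-1)
        w_s = conv1d_same(c_max, self.filt_s, pad_mode="edge").softmax(axis=-1)
        return w_c, w_s

    def __call__(self, x: Tensor) -> Tensor:
        _check_finite(x.data)
        n, c, h, w = x.data.shape
        w_c, w_s = self.attention(x)
        if self.rescale_attention:
            w_c = w_c * float(c)
            w_s = w_s * float(h * w)
        return x * w_c.reshape(n, c, 1, 1) + x * w_s.reshape(n, 1, h, w)
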