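"""Layers: 2-D convolution (im2col), 2x2 max pooling, same-padded 1-D
convolution, linear, and cross-entropy loss."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from mae.nn.autograd import Tensor


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class; parameters are discovered recursively from attributes."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for value in vars(self).values():
            items = value if isinstance(value, (list, tuple)) else [value]
            for v in items:
                if isinstance(v, Parameter) and id(v) not in seen:
                    seen.add(id(v))
                    params.append(v)
                elif isinstance(v, Module):
                    for p in v.parameters():
                        if id(p) not in seen:
                            seen.add(id(p))
                            params.append(p)
        return params

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state, strict=True):
            p.data = np.asarray(s, dtype=np.float64).copy()


def conv2d(x: Tensor, w: Tensor, pad: int = 1) -> Tensor:
    """Stride-1 zero-padded 2-D convolution. x: (N,C,H,W); w: (Cout,C,kh,kw)."""
    n, c, h, wdt = x.data.shape
    cout, cin, kh, kw = w.data.shape
    if cin != c:
        raise ValueError(f"input has {c} channels but kernel expects {cin}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho, wo = h + 2 * pad - kh + 1, wdt + 2 * pad - kw + 1
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (N,C,Ho,Wo,kh,kw)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * ho * wo, c * kh * kw
    )
    wm = w.data.reshape(cout, -1)
    out = (cols @ wm.T).reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)

    def backward(g):
        gm = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, cout)
        if w.requires_grad:
            w._accum((gm.T @ cols).reshape(w.data.shape))
        if x.requires_grad:
            dcols = (gm @ wm).reshape(n, ho, wo, c, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + ho, j : j + wo] += dcols[:, :, :, :, i, j].transpose(
                        0, 3, 1, 2
                    )
            x._accum(dxp[:, :, pad : pad + h, pad : pad + wdt])

    return Tensor._make(out, (x, w), backward)


def max_pool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; spatial dims must be even."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
    ho, wo = h // 2, w // 2
    xr = x.data.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        n, c, ho, wo, 4
    )
    idx = np.argmax(xr, axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        grad = np.zeros_like(xr)
        np.put_along_axis(grad, idx[..., None], g[..., None], axis=-1)
        x._accum(
            grad.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        )

    return Tensor._make(out, (x,), backward)


def conv1d_same(x: Tensor, w: Tensor, pad_mode: str = "zero") -> Tensor:
    """Single-filter, bias-free, length-preserving 1-D cross-correlation.

    x: (N, L); w: (k,) with k odd.  ``pad_mode`` is "zero" or "edge";
    edge-replicate padding preserves constant inputs exactly, which the
    attention module relies on.
    """
    k = w.data.shape[0]
    if k % 2 == 0:
        raise ValueError(f"kernel size must be odd, got {k}")
    if pad_mode not in ("zero", "edge"):
        raise ValueError(f"pad_mode must be 'zero' or 'edge', got {pad_mode!r}")
    n, ln = x.data.shape
    p = k // 2
    mode = "constant" if pad_mode == "zero" else "edge"
    xp = np.pad(x.data, ((0, 0), (p, p)), mode=mode)
    win = sliding_window_view(xp, k, axis=1)  # (N, L, k)
    out = win @ w.data

    def backward(g):
        if w.requires_grad:
            w._accum(np.einsum("nlk,nl->k", win, g))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for j in range(k):
                dxp[:, j : j + ln] += g * w.data[j]
            dx = dxp[:, p : p + ln].copy()
            if pad_mode == "edge":  # padded taps replicate the boundary values
                dx[:, 0] += dxp[:, :p].sum(axis=1)
                dx[:, -1] += dxp[:, p + ln :].sum(axis=1)
            x._accum(dx)

    return Tensor._make(out, (x, w), backward)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int = 3, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (cin * k * k))  # He init for ReLU stacks
        self.weight = Parameter(rng.normal(0.0, scale, size=(cout, cin, k, k)))
        self.bias = Parameter(np.zeros(cout))
        self.pad = k // 2

    def __call__(self, x: Tensor) -> Tensor:
        out = conv2d(x, self.weight, pad=self.pad)
        return out + self.bias.reshape(1, -1, 1, 1)


class Linear(Module):
    def __init__(self, din: int, dout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(1.0 / din)
        self.weight = Parameter(rng.normal(0.0, scale, size=(din, dout)))
        self.bias = Parameter(np.zeros(dout))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy between softmax(logits) and integer labels."""
    n = logits.data.shape[0]
    onehot = np.zeros_like(logits.data)
    onehot[np.arange(n), np.asarray(labels, dtype=int)] = 1.0
    return (logits.log_softmax(axis=-1) * onehot).sum() * (-1.0 / n)
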