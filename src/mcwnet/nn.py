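"""Minimal NumPy compute-graph layers with manual backpropagation.

All image tensors are NHWC float32.  Each layer owns its parameters and
gradients; ``forward`` caches whatever ``backward`` needs.  The graph engine
in :mod:`mcwnet.model` wires layers into a DAG and drives forward/backward
passes; SGDM updates live in :mod:`mcwnet.training`.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base class: parameter-free pass-through."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def init(self, rng: np.random.Generator) -> None:  # noqa: ARG002
        pass

    def forward(self, *xs: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, ...]:
        raise NotImplementedError

    def param_count(self) -> int:
        return sum(int(p.size) for p in self.params.values())


class Identity(Layer):
    """Structural no-op (sequence fold/unfold, classification output)."""

    def forward(self, x, *, train=False, rng=None):
        return x

    def backward(self, dout):
        return (dout,)


class Conv2D(Layer):
    """3x3 (by default) convolution, stride 1, padding 0 or 'same'."""

    def __init__(self, c_in: int, c_out: int, ksize: int = 3,
                 padding: int | str = 0) -> None:
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, ksize
        self.pad = ksize // 2 if padding == "same" else int(padding)
        self.params = {"W": np.zeros((ksize, ksize, c_in, c_out), dtype=F32),
                       "b": np.zeros(c_out, dtype=F32)}

    def init(self, rng):
        fan_in = self.k * self.k * self.c_in
        fan_out = self.k * self.k * self.c_out
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.params["W"] = rng.uniform(-limit, limit,
                                       self.params["W"].shape).astype(F32)
        self.params["b"] = np.zeros(self.c_out, dtype=F32)

    def forward(self, x, *, train=False, rng=None):
        if self.pad:
            x = np.pad(x, ((0, 0), (self.pad,) * 2, (self.pad,) * 2, (0, 0)))
        n, h, w, _ = x.shape
        k = self.k
        ho, wo = h - k + 1, w - k + 1
        wk = self.params["W"]
        # one GEMM per kernel offset beats im2col on a single core: the
        # patch matrix is never materialised
        out = np.ascontiguousarray(x[:, :ho, :wo, :]).reshape(-1, self.c_in) \
            @ wk[0, 0]
        for off in range(1, k * k):
            i, j = off // k, off % k
            sl = np.ascontiguousarray(x[:, i:i + ho, j:j + wo, :])
            out += sl.reshape(-1, self.c_in) @ wk[i, j]
        out += self.params["b"]
        self._xp = x
        self._dims = (n, h, w, ho, wo)
        return out.reshape(n, ho, wo, self.c_out)

    def backward(self, dout):
        x = self._xp
        n, h, w, ho, wo = self._dims
        k = self.k
        wk = self.params["W"]
        dflat = dout.reshape(-1, self.c_out)
        dW = np.empty_like(wk)
        dxp = np.zeros((n, h, w, self.c_in), dtype=F32)
        for off in range(k * k):
            i, j = off // k, off % k
            sl = np.ascontiguousarray(x[:, i:i + ho, j:j + wo, :])
            dW[i, j] = sl.reshape(-1, self.c_in).T @ dflat
            dxp[:, i:i + ho, j:j + wo, :] += (dflat @ wk[i, j].T).reshape(
                n, ho, wo, self.c_in)
        self.grads["W"] = dW
        self.grads["b"] = dflat.sum(axis=0)
        if self.pad:
            dxp = dxp[:, self.pad:-self.pad, self.pad:-self.pad, :]
        return (dxp,)


class BatchNorm2D(Layer):
    """Per-channel batch normalisation with running statistics for inference."""

    def __init__(self, channels: int, eps: float = 1e-5,
                 momentum: float = 0.1) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params = {"gamma": np.ones(channels, dtype=F32),
                       "beta": np.zeros(channels, dtype=F32)}
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)

    def forward(self, x, *, train=False, rng=None):
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(F32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv.astype(F32), x.shape)
        return (xhat * self.params["gamma"] + self.params["beta"]).astype(F32)

    def backward(self, dout):
        xhat, inv, shape = self._cache
        m = shape[0] * shape[1] * shape[2]
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 1, 2))
        self.grads["beta"] = dout.sum(axis=(0, 1, 2))
        dxhat = dout * self.params["gamma"]
        dx = (inv / m) * (m * dxhat
                          - dxhat.sum(axis=(0, 1, 2))
                          - xhat * (dxhat * xhat).sum(axis=(0, 1, 2)))
        return (dx.astype(F32),)


class ReLU(Layer):
    def forward(self, x, *, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(F32)

    def backward(self, dout):
        return ((dout * self._mask).astype(F32),)


class Sigmoid(Layer):
    def forward(self, x, *, train=False, rng=None):
        self._out = sigmoid(x).astype(F32)
        return self._out

    def backward(self, dout):
        return ((dout * self._out * (1.0 - self._out)).astype(F32),)


class MaxPool2D(Layer):
    """k x k max pooling with stride 1 and padding 0."""

    def __init__(self, ksize: int = 3) -> None:
        super().__init__()
        self.k = ksize

    def forward(self, x, *, train=False, rng=None):
        n, h, w, c = x.shape
        k = self.k
        ho, wo = h - k + 1, w - k + 1
        best = x[:, :ho, :wo, :].copy()
        arg = np.zeros((n, ho, wo, c), dtype=np.int8)
        for off in range(1, k * k):
            i, j = off // k, off % k
            cand = x[:, i:i + ho, j:j + wo, :]
            better = cand > best
            np.copyto(best, cand, where=better)
            arg[better] = off
        self._argmax = arg
        self._inshape = x.shape
        return best

    def backward(self, dout):
        n, h, w, c = self._inshape
        k = self.k
        ho, wo = h - k + 1, w - k + 1
        ni, ii, ji, ci = np.indices((n, ho, wo, c), sparse=True)
        ky, kx = self._argmax // k, self._argmax % k
        flat = (((ni * h + ii + ky) * w) + (ji + kx)) * c + ci
        dx = np.bincount(flat.ravel(), weights=dout.ravel().astype(np.float64),
                         minlength=n * h * w * c)
        return (dx.reshape(n, h, w, c).astype(F32),)


class Multiply(Layer):
    """Element-wise multiplication of two inputs.

    Shapes must match exactly, except that the first input may have a single
    channel broadcast over the second's channels (the alpha map case).
    """

    def forward(self, a, b, *, train=False, rng=None):
        if a.shape != b.shape and not (a.shape[:-1] == b.shape[:-1]
                                       and a.shape[-1] == 1):
            raise ValueError(f"multiply shape mismatch: {a.shape} vs {b.shape}")
        self._a, self._b = a, b
        return (a * b).astype(F32)

    def backward(self, dout):
        da = dout * self._b
        db = dout * self._a
        if self._a.shape != self._b.shape:  # broadcast alpha: reduce channels
            da = da.sum(axis=-1, keepdims=True)
        return (da.astype(F32), db.astype(F32))


class CenterCrop(Layer):
    """Crop spatial dims to a target (used to align the additive gating signal)."""

    def __init__(self, target_hw: tuple[int, int]) -> None:
        super().__init__()
        self.target = target_hw

    def forward(self, x, *, train=False, rng=None):
        th, tw = self.target
        h, w = x.shape[1], x.shape[2]
        y0, x0 = (h - th) // 2, (w - tw) // 2
        self._pads = (x.shape, y0, x0)
        return x[:, y0:y0 + th, x0:x0 + tw, :]

    def backward(self, dout):
        shape, y0, x0 = self._pads
        dx = np.zeros(shape, dtype=F32)
        dx[:, y0:y0 + dout.shape[1], x0:x0 + dout.shape[2], :] = dout
        return (dx,)


class AttentionGate(Layer):
    """Additive attention gate: alpha = sigma(phi^T(wx^T x + wg^T g + bg) + bphi).

    ``wx``/``wg``/``phi`` are 1x1 channel-mixing convolutions; the output is
    the per-pixel coefficient map alpha (N,H,W,1), to be multiplied with the
    feature map by a downstream :class:`Multiply` node.
    """

    def __init__(self, c_x: int, c_g: int, c_inter: int) -> None:
        super().__init__()
        self.c_x, self.c_g, self.c_inter = c_x, c_g, c_inter
        self.params = {"wx": np.zeros((c_x, c_inter), dtype=F32),
                       "wg": np.zeros((c_g, c_inter), dtype=F32),
                       "bg": np.zeros(c_inter, dtype=F32),
                       "phi": np.zeros((c_inter, 1), dtype=F32),
                       "bphi": np.zeros(1, dtype=F32)}

    def init(self, rng):
        for key, (fi, fo) in (("wx", (self.c_x, self.c_inter)),
                              ("wg", (self.c_g, self.c_inter)),
                              ("phi", (self.c_inter, 1))):
            limit = np.sqrt(6.0 / (fi + fo))
            self.params[key] = rng.uniform(-limit, limit,
                                           self.params[key].shape).astype(F32)

    def forward(self, x, g, *, train=False, rng=None):
        inter = (x @ self.params["wx"] + g @ self.params["wg"]
                 + self.params["bg"])
        s = inter @ self.params["phi"] + self.params["bphi"]
        alpha = sigmoid(s)
        self._cache = (x, g, inter, alpha)
        return alpha.astype(F32)

    def backward(self, dout):
        x, g, inter, alpha = self._cache
        ds = dout * alpha * (1.0 - alpha)
        self.grads["bphi"] = np.array([ds.sum()], dtype=F32)
        flat_inter = inter.reshape(-1, self.c_inter)
        flat_ds = ds.reshape(-1, 1)
        self.grads["phi"] = flat_inter.T @ flat_ds
        dinter = (flat_ds @ self.params["phi"].T).reshape(inter.shape)
        self.grads["bg"] = dinter.reshape(-1, self.c_inter).sum(axis=0)
        fx = x.reshape(-1, self.c_x)
        fg = g.reshape(-1, self.c_g)
        fdi = dinter.reshape(-1, self.c_inter)
        self.grads["wx"] = fx.T @ fdi
        self.grads["wg"] = fg.T @ fdi
        dx = (fdi @ self.params["wx"].T).reshape(x.shape)
        dg = (fdi @ self.params["wg"].T).reshape(g.shape)
        return (dx.astype(F32), dg.astype(F32))


class Flatten(Layer):
    def forward(self, x, *, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return (dout.reshape(self._shape),)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int) -> None:
        super().__init__()
        self.d_in, self.d_out = d_in, d_out
        self.params = {"W": np.zeros((d_in, d_out), dtype=F32),
                       "b": np.zeros(d_out, dtype=F32)}

    def init(self, rng):
        limit = np.sqrt(6.0 / (self.d_in + self.d_out))
        self.params["W"] = rng.uniform(-limit, limit,
                                       (self.d_in, self.d_out)).astype(F32)
        self.params["b"] = np.zeros(self.d_out, dtype=F32)

    def forward(self, x, *, train=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return ((dout @ self.params["W"].T).astype(F32),)


class Dropout(Layer):
    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, *, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return (x * self._mask).astype(F32)

    def backward(self, dout):
        if self._mask is None:
            return (dout,)
        return ((dout * self._mask).astype(F32),)


class LSTMStep(Layer):
    """Single-step LSTM over a length-1 sequence (one image per sequence).

    Gates follow the peephole-style concatenation ``[x, h_prev, C_prev]``;
    the candidate uses a weighted tanh.  The initial state is zero, so only
    the ``x`` block of each gate matrix influences this one step, but full
    matrices are kept so the layer is a faithful general cell.
    """

    def __init__(self, d_in: int, hidden: int) -> None:
        super().__init__()
        self.d_in, self.hidden = d_in, hidden
        d_cat = d_in + 2 * hidden
        # gate order: f, i, c(candidate), o — stacked for one matmul
        self.params = {"W": np.zeros((d_cat, 4 * hidden), dtype=F32),
                       "b": np.zeros(4 * hidden, dtype=F32)}

    def init(self, rng):
        # Glorot uniform with fan-out = all four gates, the source
        # framework's default for LSTM input weights
        d_cat = self.d_in + 2 * self.hidden
        limit = np.sqrt(6.0 / (d_cat + 4 * self.hidden))
        self.params["W"] = rng.uniform(-limit, limit,
                                       self.params["W"].shape).astype(F32)
        self.params["b"] = np.zeros(4 * self.hidden, dtype=F32)

    def forward(self, x, *, train=False, rng=None):
        n = x.shape[0]
        hdim = self.hidden
        z = np.concatenate(
            [x, np.zeros((n, 2 * hdim), dtype=F32)], axis=1)
        pre = z @ self.params["W"] + self.params["b"]
        f = sigmoid(pre[:, :hdim])
        i = sigmoid(pre[:, hdim:2 * hdim])
        cand = np.tanh(pre[:, 2 * hdim:3 * hdim])
        o = sigmoid(pre[:, 3 * hdim:])
        c_new = i * cand  # f * C_prev vanishes at zero initial state
        tanh_c = np.tanh(c_new)
        h = o * tanh_c
        self._cache = (z, f, i, cand, o, tanh_c)
        return h.astype(F32)

    def backward(self, dout):
        z, f, i, cand, o, tanh_c = self._cache
        hdim = self.hidden
        do = dout * tanh_c
        dc = dout * o * (1.0 - tanh_c ** 2)
        di = dc * cand
        dcand = dc * i
        df = np.zeros_like(f)  # dC/df = C_prev = 0
        dpre = np.concatenate([df * f * (1 - f),
                               di * i * (1 - i),
                               dcand * (1 - cand ** 2),
                               do * o * (1 - o)], axis=1).astype(F32)
        self.grads["W"] = z.T @ dpre
        self.grads["b"] = dpre.sum(axis=0)
        dz = dpre @ self.params["W"].T
        return (dz[:, :self.d_in].astype(F32),)


class Softmax(Layer):
    def forward(self, x, *, train=False, rng=None):
        shifted = x - x.max(axis=-1, keepdims=True)
        e = np.exp(shifted)
        self._out = (e / e.sum(axis=-1, keepdims=True)).astype(F32)
        return self._out

    def backward(self, dout):
        p = self._out
        dot = (dout * p).sum(axis=-1, keepdims=True)
        return ((p * (dout - dot)).astype(F32),)
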