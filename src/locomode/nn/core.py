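"""Layers, loss and optimizers for the locomotion classifiers.

All computation is float32.  Convolutions use im2col with "same" padding and
stride 1; their input gradient is the full correlation of the output
gradient with the flipped kernels, computed with the same im2col machinery.
Recurrent layers run plain backpropagation through time over the (short)
frame axis.  Weight initialization is Glorot-uniform from a caller-supplied
seeded generator, so models are reproducible.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


def _orthogonal_gates(rng: np.random.Generator, units: int, n_gates: int) -> np.ndarray:
    """Recurrent weight init: one orthogonal block per gate (units, units).

    Orthogonal recurrent matrices preserve signal norms through time and
    are the standard initialization for LSTM/GRU recurrent kernels.
    """
    blocks = []
    for _ in range(n_gates):
        a = rng.normal(size=(units, units))
        q, r = np.linalg.qr(a)
        q *= np.sign(np.diag(r))  # make the factorization unique
        blocks.append(q)
    return np.concatenate(blocks, axis=1).astype(F32)


class Layer:
    params: list[Param]

    def __init__(self) -> None:
        self.params = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) zero-padded same -> (B*H*W, C*k*k)."""
    b, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # (B, C, H, W, k, k) -> (B, H, W, C, k, k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * w, c * k * k)
    return np.ascontiguousarray(cols, dtype=F32)


class Conv2D(Layer):
    """Stride-1 "same" 2-D convolution (cross-correlation), k x k kernel.

    ``skip_input_grad`` elides the input-gradient computation; set it on the
    first layer of a stack, whose input gradient nobody consumes.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 skip_input_grad: bool = False):
        super().__init__()
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        self.skip_input_grad = skip_input_grad
        fan_in = in_ch * kernel * kernel
        fan_out = out_ch * kernel * kernel
        self.w = Param(_glorot(rng, (in_ch * kernel * kernel, out_ch), fan_in, fan_out))
        self.b = Param(np.zeros(out_ch, dtype=F32))
        self.params = [self.w, self.b]
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x, train=False):
        b, c, h, w = x.shape
        cols = _im2col(x, self.k)
        y = cols @ self.w.value + self.b.value
        if train:
            self._cols, self._shape = cols, x.shape
        return np.ascontiguousarray(
            y.reshape(b, h, w, self.out_ch).transpose(0, 3, 1, 2)
        )

    def backward(self, dout):
        b, c, h, w = self._shape
        dy = np.ascontiguousarray(dout.transpose(0, 2, 3, 1), dtype=F32)  # NHWC
        dmat = dy.reshape(b * h * w, self.out_ch)
        self.w.grad += self._cols.T @ dmat
        self.b.grad += dmat.sum(axis=0)
        self._cols = None
        if self.skip_input_grad:
            return None
        # input gradient by shift-accumulate: for every kernel offset, one
        # GEMM against that offset's weight slice, added into the padded
        # gradient at the shifted position (adjoint of the forward gather)
        k, p = self.k, self.k // 2
        wk = self.w.value.reshape(self.in_ch, k, k, self.out_ch)
        dxp = np.zeros((b, h + 2 * p, w + 2 * p, self.in_ch), dtype=F32)
        for di in range(k):
            for dj in range(k):
                dxp[:, di:di + h, dj:dj + w, :] += dy @ wk[:, di, dj, :].T
        return np.ascontiguousarray(
            dxp[:, p:p + h, p:p + w, :].transpose(0, 3, 1, 2)
        )


class MaxPool2D(Layer):
    """2x2 max pooling with stride 2; trailing odd rows/columns are dropped."""

    def __init__(self, size: int = 2):
        super().__init__()
        self.s = size
        self._cache = None

    def forward(self, x, train=False):
        s = self.s
        b, c, h, w = x.shape
        h2, w2 = h // s, w // s
        xc = x[:, :, : h2 * s, : w2 * s]
        blocks = xc.reshape(b, c, h2, s, w2, s).transpose(0, 1, 2, 4, 3, 5).reshape(
            b, c, h2, w2, s * s
        )
        idx = np.argmax(blocks, axis=-1)
        out = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (x.shape, idx)
        return np.ascontiguousarray(out, dtype=F32)

    def backward(self, dout):
        (b, c, h, w), idx = self._cache
        s = self.s
        h2, w2 = h // s, w // s
        dblocks = np.zeros((b, c, h2, w2, s * s), dtype=F32)
        np.put_along_axis(dblocks, idx[..., None], dout[..., None].astype(F32), axis=-1)
        dx = np.zeros((b, c, h, w), dtype=F32)
        dx[:, :, : h2 * s, : w2 * s] = (
            dblocks.reshape(b, c, h2, w2, s, s).transpose(0, 1, 2, 4, 3, 5).reshape(
                b, c, h2 * s, w2 * s
            )
        )
        self._cache = None
        return dx


class Center(Layer):
    """Fixed affine input map ``(x - offset) * scale`` (no parameters).

    The mel images live in [0, 1]; centering them to [-1, 1] removes the
    all-positive input bias that slows early convolution training.
    """

    def __init__(self, offset: float = 0.5, scale: float = 2.0):
        super().__init__()
        self.offset = F32(offset)
        self.scale = F32(scale)

    def forward(self, x, train=False):
        return (x - self.offset) * self.scale

    def backward(self, dout):
        return dout * self.scale


class Activation(Layer):
    """Elementwise nonlinearity: relu, elu or tanh."""

    def __init__(self, kind: str):
        super().__init__()
        if kind not in ("relu", "elu", "tanh"):
            raise ValueError(f"unknown activation {kind!r}")
        self.kind = kind
        self._cache = None

    def forward(self, x, train=False):
        if self.kind == "relu":
            y = np.maximum(x, 0)
        elif self.kind == "tanh":
            y = np.tanh(x)
        else:  # elu, alpha = 1
            y = np.where(x > 0, x, np.expm1(np.minimum(x, 0)))
        if train:
            self._cache = (x, y)
        return y.astype(F32, copy=False)

    def backward(self, dout):
        x, y = self._cache
        if self.kind == "relu":
            dx = dout * (x > 0)
        elif self.kind == "tanh":
            dx = dout * (1 - y * y)
        else:
            dx = dout * np.where(x > 0, 1.0, y + 1.0)
        self._cache = None
        return dx.astype(F32, copy=False)


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate).astype(F32) / F32(
            1 - self.rate
        )
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        dx = dout * self._mask
        self._mask = None
        return dx


class Flatten(Layer):
    def __init__(self):
        super().__init__()
        self._shape = None

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class FramesAsTime(Layer):
    """(B, filters, rows, frames) -> (B, frames, filters * rows).

    Turns the pooled frame axis into the recurrent time axis, with the
    surviving mel rows times the filters as per-step features.
    """

    def __init__(self):
        super().__init__()
        self._shape = None

    def forward(self, x, train=False):
        b, c, h, w = x.shape
        self._shape = x.shape
        return np.ascontiguousarray(
            x.transpose(0, 3, 1, 2).reshape(b, w, c * h), dtype=F32
        )

    def backward(self, dout):
        b, c, h, w = self._shape
        return np.ascontiguousarray(
            dout.reshape(b, w, c, h).transpose(0, 2, 3, 1), dtype=F32
        )


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.w = Param(_glorot(rng, (in_dim, out_dim), in_dim, out_dim))
        self.b = Param(np.zeros(out_dim, dtype=F32))
        self.params = [self.w, self.b]
        self._x = None

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout):
        dout = dout.astype(F32, copy=False)
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        dx = dout @ self.w.value.T
        self._x = None
        return dx


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class LSTM(Layer):
    """LSTM over (B, T, D) inputs; gate order i, f, g, o; forget bias 1."""

    def __init__(self, in_dim: int, units: int, rng: np.random.Generator,
                 return_sequences: bool = False):
        super().__init__()
        self.units = units
        self.return_sequences = return_sequences
        h = units
        self.wx = Param(_glorot(rng, (in_dim, 4 * h), in_dim, 4 * h))
        self.wh = Param(_orthogonal_gates(rng, h, 4))
        b = np.zeros(4 * h, dtype=F32)
        b[h:2 * h] = 1.0
        self.b = Param(b)
        self.params = [self.wx, self.wh, self.b]
        self._cache = None

    def forward(self, x, train=False):
        b, t, d = x.shape
        h = self.units
        hs = np.zeros((b, t + 1, h), dtype=F32)
        cs = np.zeros((b, t + 1, h), dtype=F32)
        gates = np.zeros((b, t, 4 * h), dtype=F32)
        for step in range(t):
            z = x[:, step] @ self.wx.value + hs[:, step] @ self.wh.value + self.b.value
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h:2 * h])
            g = np.tanh(z[:, 2 * h:3 * h])
            o = _sigmoid(z[:, 3 * h:])
            cs[:, step + 1] = f * cs[:, step] + i * g
            hs[:, step + 1] = o * np.tanh(cs[:, step + 1])
            gates[:, step] = np.concatenate([i, f, g, o], axis=1)
        if train:
            self._cache = (x, hs, cs, gates)
        return hs[:, 1:] if self.return_sequences else hs[:, -1]

    def backward(self, dout):
        x, hs, cs, gates = self._cache
        b, t, d = x.shape
        h = self.units
        dx = np.zeros_like(x)
        dh_next = np.zeros((b, h), dtype=F32)
        dc_next = np.zeros((b, h), dtype=F32)
        for step in range(t - 1, -1, -1):
            dh = dh_next.copy()
            if self.return_sequences:
                dh += dout[:, step]
            elif step == t - 1:
                dh += dout
            i = gates[:, step, :h]
            f = gates[:, step, h:2 * h]
            g = gates[:, step, 2 * h:3 * h]
            o = gates[:, step, 3 * h:]
            c = cs[:, step + 1]
            tanh_c = np.tanh(c)
            do = dh * tanh_c
            dc = dh * o * (1 - tanh_c * tanh_c) + dc_next
            di = dc * g
            df = dc * cs[:, step]
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            ).astype(F32)
            self.wx.grad += x[:, step].T @ dz
            self.wh.grad += hs[:, step].T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, step] = dz @ self.wx.value.T
            dh_next = dz @ self.wh.value.T
            dc_next = dc * f
        self._cache = None
        return dx


class GRU(Layer):
    """GRU over (B, T, D) inputs; gate order z (update), r (reset), h~."""

    def __init__(self, in_dim: int, units: int, rng: np.random.Generator,
                 return_sequences: bool = False):
        super().__init__()
        self.units = units
        self.return_sequences = return_sequences
        h = units
        self.wx = Param(_glorot(rng, (in_dim, 3 * h), in_dim, 3 * h))
        self.wh = Param(_orthogonal_gates(rng, h, 3))
        self.b = Param(np.zeros(3 * h, dtype=F32))
        self.params = [self.wx, self.wh, self.b]
        self._cache = None

    def forward(self, x, train=False):
        b, t, d = x.shape
        h = self.units
        hs = np.zeros((b, t + 1, h), dtype=F32)
        zs = np.zeros((b, t, 3 * h), dtype=F32)  # z, r, hcand
        for step in range(t):
            ax = x[:, step] @ self.wx.value + self.b.value
            ah = hs[:, step] @ self.wh.value
            z = _sigmoid(ax[:, :h] + ah[:, :h])
            r = _sigmoid(ax[:, h:2 * h] + ah[:, h:2 * h])
            hcand = np.tanh(ax[:, 2 * h:] + r * ah[:, 2 * h:])
            hs[:, step + 1] = (1 - z) * hs[:, step] + z * hcand
            zs[:, step] = np.concatenate([z, r, hcand], axis=1)
        if train:
            self._cache = (x, hs, zs)
        return hs[:, 1:] if self.return_sequences else hs[:, -1]

    def backward(self, dout):
        x, hs, zs = self._cache
        b, t, d = x.shape
        h = self.units
        dx = np.zeros_like(x)
        dh_next = np.zeros((b, h), dtype=F32)
        for step in range(t - 1, -1, -1):
            dh = dh_next.copy()
            if self.return_sequences:
                dh += dout[:, step]
            elif step == t - 1:
                dh += dout
            z = zs[:, step, :h]
            r = zs[:, step, h:2 * h]
            hcand = zs[:, step, 2 * h:]
            h_prev = hs[:, step]
            ah_c = h_prev @ self.wh.value[:, 2 * h:]
            dz_gate = dh * (hcand - h_prev) * z * (1 - z)
            dhcand = dh * z * (1 - hcand * hcand)
            dr = dhcand * ah_c * r * (1 - r)
            dzx = np.concatenate([dz_gate, dr, dhcand], axis=1).astype(F32)
            self.wx.grad += x[:, step].T @ dzx
            self.b.grad += dzx.sum(axis=0)
            # recurrent weight grads: candidate column sees r * h_prev
            dah = np.concatenate([dz_gate, dr, dhcand * r], axis=1).astype(F32)
            self.wh.grad += h_prev.T @ dah
            dx[:, step] = dzx @ self.wx.value.T
            dh_next = dh * (1 - z) + dah @ self.wh.value.T
        self._cache = None
        return dx


class Sequential:
    """A plain layer stack producing logits; softmax lives in the loss."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.ascontiguousarray(x, dtype=F32)
        for layer in self.layers:
            out = layer.forward(out, train=train)
        return out

    def backward(self, dlogits: np.ndarray) -> np.ndarray | None:
        dout = dlogits
        for layer in reversed(self.layers):
            if dout is None:  # a layer elided its input gradient
                break
            dout = layer.backward(dout)
        return dout

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        if len(weights) != len(self.params):
            raise ValueError("weight list length mismatch")
        for p, w in zip(self.params, weights):
            if p.value.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.value.shape} vs {w.shape}")
            p.value[...] = w

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params)


def clip_gradients(params: list[Param], max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``.

    Returns the pre-clip norm.  Standard stabilizer for recurrent nets.
    """
    total = float(np.sqrt(sum(float(np.sum(p.grad.astype(np.float64) ** 2))
                              for p in params)))
    if total > max_norm > 0:
        factor = F32(max_norm / (total + 1e-12))
        for p in params:
            p.grad *= factor
    return total


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray,
    targets: np.ndarray,
    sample_weights: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Weighted categorical cross-entropy and its logit gradient.

    ``targets`` are integer class indices.  The loss is the weighted mean
    ``sum_i w_i * ce_i / sum_i w_i``, so equal weights reduce exactly to the
    unweighted mean.  Returns ``(loss, dlogits)``.
    """
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    eps = 1e-12
    ce = -np.log(p[np.arange(n), targets] + eps)
    if sample_weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(sample_weights, dtype=np.float64)
    wsum = w.sum()
    loss = float((w * ce).sum() / wsum)
    dlogits = p
    dlogits[np.arange(n), targets] -= 1.0
    dlogits *= (w / wsum)[:, None]
    return loss, dlogits.astype(F32)


class Adam:
    """Adam optimizer with bias correction."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class RMSProp:
    """RMSProp optimizer (running mean of squared gradients)."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 rho: float = 0.9, eps: float = 1e-7):
        self.params = params
        self.lr, self.rho, self.eps = lr, rho, eps
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self.v):
            g = p.grad
            v *= self.rho
            v += (1 - self.rho) * g * g
            p.value -= self.lr * g / (np.sqrt(v) + self.eps)
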