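"""Minimal CPU neural-network core for heatmap regression.

Implements exactly the pieces the landmark-detection U-Net needs, in NHWC
float32 with explicit backpropagation: 3x3 same-padded convolution (as an
im2col matrix product so the heavy lifting is BLAS sgemm), 1x1 convolution,
2x2 max pooling, 2x2 stride-2 transposed convolution, inverted dropout,
channel concatenation, per-pixel softmax cross-entropy, and Adam.

Weights use He-normal initialisation; ReLU activations are fused into the
convolution layers. All randomness (init, dropout) flows through a single
``numpy.random.Generator`` so runs are reproducible on one thread.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def _conv3p(xp: np.ndarray, w9: np.ndarray) -> np.ndarray:
    """Same-padded 3x3 convolution of an already-padded input.

    ``w9`` has shape (9, cin, cout), offsets in (ky, kx) row-major order.
    Each offset contributes one batched matrix product on a shifted view --
    far faster on CPU than materialising an im2col patch matrix.
    """
    n, hp, wp, cin = xp.shape
    h, w = hp - 2, wp - 2
    y = np.zeros((n, h, w, w9.shape[2]), dtype=F32)
    k = 0
    for ky in range(3):
        for kx in range(3):
            y += np.matmul(xp[:, ky : ky + h, kx : kx + w, :], w9[k])
            k += 1
    return y


def _pad1(x: np.ndarray, buf: np.ndarray | None = None) -> np.ndarray:
    """Zero-pad by one pixel on each spatial border, reusing ``buf`` if it fits."""
    n, h, w, c = x.shape
    if buf is None or buf.shape != (n, h + 2, w + 2, c):
        buf = np.zeros((n, h + 2, w + 2, c), dtype=x.dtype)
    buf[:, 1:-1, 1:-1, :] = x
    return buf


class Conv3x3:
    """3x3 same-padded convolution, optional fused ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, relu: bool = True):
        std = np.sqrt(2.0 / (9 * cin))
        self.w = rng.normal(0.0, std, size=(3, 3, cin, cout)).astype(F32)
        self.b = np.zeros(cout, dtype=F32)
        self.relu = relu
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._xp = _pad1(x, getattr(self, "_pbuf", None))
        self._pbuf = self._xp
        y = _conv3p(self._xp, self.w.reshape(9, *self.w.shape[2:]))
        y += self.b
        if self.relu:
            np.maximum(y, 0, out=y)
            self._mask = y > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.relu:
            dy = dy * self._mask
        n, h, w, cout = dy.shape
        xp = self._xp
        for ky in range(3):
            for kx in range(3):
                v = xp[:, ky : ky + h, kx : kx + w, :]
                self.gw[ky, kx] = np.matmul(v.swapaxes(-1, -2), dy).sum(axis=(0, 1))
        self.gb[...] = dy.sum(axis=(0, 1, 2))
        # grad wrt input = same-padded conv of dy with the rotated kernel
        wr = self.w[::-1, ::-1].transpose(0, 1, 3, 2).reshape(9, cout, -1)
        self._dbuf = _pad1(dy, getattr(self, "_dbuf", None))
        dx = _conv3p(self._dbuf, np.ascontiguousarray(wr))
        self._xp = None
        return dx


class Conv1x1:
    """1x1 convolution head (no activation; softmax lives in the loss)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / cin)
        self.w = rng.normal(0.0, std, size=(cin, cout)).astype(F32)
        self.b = np.zeros(cout, dtype=F32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, cout = dy.shape
        xf = self._x.reshape(-1, self.w.shape[0])
        dyf = dy.reshape(-1, cout)
        self.gw[...] = xf.T @ dyf
        self.gb[...] = dyf.sum(axis=0)
        self._x = None
        return (dyf @ self.w.T).reshape(n, h, w, -1)


class MaxPool2x2:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        r = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        r = r.reshape(n, h // 2, w // 2, 4, c)
        self._idx = r.argmax(axis=3)
        self._shape = (n, h, w, c)
        return np.take_along_axis(r, self._idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        out = np.zeros((n, h // 2, w // 2, 4, c), dtype=dy.dtype)
        np.put_along_axis(out, self._idx[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
        return (
            out.reshape(n, h // 2, w // 2, 2, 2, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(n, h, w, c)
        )


class ConvT2x2:
    """2x2 stride-2 transposed convolution (learned upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / cin)
        self.w = rng.normal(0.0, std, size=(cin, 4 * cout)).astype(F32)
        self.b = np.zeros(cout, dtype=F32)
        self.cout = cout
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, cin = x.shape
        self._x = x
        y = (x.reshape(-1, cin) @ self.w).reshape(n, h, w, 2, 2, self.cout)
        y = y.transpose(0, 1, 3, 2, 4, 5).reshape(n, 2 * h, 2 * w, self.cout)
        return y + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h2, w2, cout = dy.shape
        h, w = h2 // 2, w2 // 2
        cin = self._x.shape[-1]
        dyf = (
            dy.reshape(n, h, 2, w, 2, cout)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(-1, 4 * cout)
        )
        self.gw[...] = self._x.reshape(-1, cin).T @ dyf
        self.gb[...] = dy.reshape(-1, cout).sum(axis=0)
        self._x = None
        return (dyf @ self.w.T).reshape(n, h, w, cin)


class Dropout:
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = float(p)
        self.rng = rng

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        mask = (self.rng.random(x.shape, dtype=F32) >= self.p).astype(F32)
        mask /= F32(1 - self.p)
        self._mask = mask
        return x * mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    """Per-pixel softmax over the last (channel) axis."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    e /= e.sum(axis=-1, keepdims=True)
    return e


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean per-pixel categorical cross-entropy and its gradient.

    The loss is the sum over channels of ``-t * log p`` averaged over every
    pixel of the batch, so its scale is independent of image resolution and
    batch size. Returns ``(loss, dlogits)``.
    """
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    s = e.sum(axis=-1, keepdims=True)
    logp = z - np.log(s)
    npix = logits.shape[0] * logits.shape[1] * logits.shape[2]
    loss = float(-(targets * logp).sum() / npix)
    dlogits = (e / s - targets) / F32(npix)
    return loss, dlogits.astype(F32)


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params  # list of (value, grad) array pairs
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * np.square(g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class UNet:
    """Encoder-decoder with skip connections for per-pixel classification.

    ``levels`` resolution levels; two 3x3 conv + ReLU per level with a dropout
    after the first; feature width doubles per level from ``base_filters``;
    2x2 max-pool down, 2x2 transposed conv up (halving features), same-level
    encoder maps concatenated before the decoder convs; 1x1 conv head with
    ``out_channels`` logits (softmax applied in the loss / at prediction).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        levels: int,
        base_filters: int,
        encoder_dropouts,
        decoder_dropouts,
        rng: np.random.Generator,
    ):
        if len(encoder_dropouts) != levels or len(decoder_dropouts) != levels - 1:
            raise ValueError("dropout schedules must have lengths levels and levels-1")
        self.levels = levels
        widths = [base_filters * 2**i for i in range(levels)]
        self.enc = []
        cin = in_channels
        for i in range(levels):
            c1 = Conv3x3(cin, widths[i], rng)
            dp = Dropout(encoder_dropouts[i], rng)
            c2 = Conv3x3(widths[i], widths[i], rng)
            self.enc.append((c1, dp, c2))
            cin = widths[i]
        self.pools = [MaxPool2x2() for _ in range(levels - 1)]
        self.dec = []
        for j, i in enumerate(range(levels - 2, -1, -1)):
            up = ConvT2x2(widths[i + 1], widths[i], rng)
            c1 = Conv3x3(2 * widths[i], widths[i], rng)
            dp = Dropout(decoder_dropouts[j], rng)
            c2 = Conv3x3(widths[i], widths[i], rng)
            self.dec.append((up, c1, dp, c2))
        self.head = Conv1x1(widths[0], out_channels, rng)

    # -- parameter plumbing -------------------------------------------------
    def layers(self):
        for blk in self.enc:
            yield from blk
        yield from self.pools
        for blk in self.dec:
            yield from blk
        yield self.head

    def params(self):
        out = []
        for layer in self.layers():
            out.extend(layer.params())
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params()]

    def set_weights(self, weights) -> None:
        params = self.params()
        if len(weights) != len(params):
            raise ValueError("weight list does not match network topology")
        for (p, _), w in zip(params, weights):
            p[...] = w

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        skips = []
        for i in range(self.levels):
            c1, dp, c2 = self.enc[i]
            x = c2.forward(dp.forward(c1.forward(x, train), train), train)
            if i < self.levels - 1:
                skips.append(x)
                x = self.pools[i].forward(x, train)
        self._skip_channels = []
        for (up, c1, dp, c2), skip in zip(self.dec, reversed(skips)):
            x = up.forward(x, train)
            self._skip_channels.append(skip.shape[-1])
            x = np.concatenate([skip, x], axis=-1)
            x = c2.forward(dp.forward(c1.forward(x, train), train), train)
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.head.backward(dlogits)
        dskips = []
        for (up, c1, dp, c2), cs in zip(reversed(self.dec), reversed(self._skip_channels)):
            d = c1.backward(dp.backward(c2.backward(dx)))
            dskips.append(d[..., :cs])
            dx = up.backward(d[..., cs:])
        for i in range(self.levels - 1, -1, -1):
            c1, dp, c2 = self.enc[i]
            if i < self.levels - 1:
                dx = self.pools[i].backward(dx)
                dx = dx + dskips[i]
            dx = c1.backward(dp.backward(c2.backward(dx)))
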