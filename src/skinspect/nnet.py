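"""Minimal feed-forward network machinery (numpy, explicit gradients).

Shared by the deterministic regressors and the forward emulator: dense /
ReLU / dropout / 1-D convolution / max-pool layers with hand-derived
backprop, an Adam optimizer, and the common training protocol (mean squared
error, batch 100, 150 epochs, learning rate 1e-3 dropped to 1e-4 after
epoch 100). Training runs in float32; predictions are returned as float64.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class TrainConfig:
    """Common optimisation schedule for all network models."""

    epochs: int = 150
    batch_size: int = 100
    lr: float = 1e-3
    lr_late: float = 1e-4
    lr_switch_epoch: int = 100
    grad_clip: float | None = None
    seed: int = 0

    def lr_at(self, epoch: int) -> float:
        return self.lr if epoch < self.lr_switch_epoch else self.lr_late


class Adam:
    def __init__(self, params: list[np.ndarray], beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.params = params
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, grads: list[np.ndarray], lr: float,
             clip: float | None = None):
        if clip is not None:
            norm = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
            if norm > clip:
                grads = [g * (clip / norm) for g in grads]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Dense:
    def __init__(self, n_in, n_out, rng, w_scale: float | None = None):
        scale = np.sqrt(2.0 / n_in) if w_scale is None else w_scale
        self.w = (rng.standard_normal((n_in, n_out)) * scale
                  ).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.w + self.b

    def backward(self, g):
        self.gw = self._x.T @ g
        self.gb = g.sum(axis=0)
        return g @ self.w.T

    def grads(self):
        return [self.gw, self.gb]


class ReLU:
    def params(self):
        return []

    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask

    def grads(self):
        return []


class Dropout:
    """Inverted dropout: active only during training."""

    def __init__(self, p, rng):
        self.p = p
        self.rng = rng

    def params(self):
        return []

    def forward(self, x, train):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(np.float32) \
            / (1.0 - self.p)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask

    def grads(self):
        return []


class Flatten:
    def params(self):
        return []

    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)

    def grads(self):
        return []


class Conv1D:
    """Same-padded 1-D convolution on (batch, length, channels) tensors."""

    def __init__(self, c_in, c_out, kernel, rng):
        self.kernel = kernel
        fan_in = kernel * c_in
        self.w = (rng.standard_normal((kernel * c_in, c_out))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.c_in = c_in

    def params(self):
        return [self.w, self.b]

    def _im2col(self, x):
        b, length, c = x.shape
        k = self.kernel
        pad = k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        cols = np.empty((b, length, k * c), dtype=x.dtype)
        for i in range(k):
            cols[:, :, i * c:(i + 1) * c] = xp[:, i:i + length, :]
        return cols

    def forward(self, x, train):
        self._x_shape = x.shape
        self._cols = self._im2col(x)
        return self._cols @ self.w + self.b

    def backward(self, g):
        b, length, c = self._x_shape
        k, pad = self.kernel, self.kernel // 2
        self.gw = np.tensordot(self._cols, g, axes=([0, 1], [0, 1]))
        self.gb = g.sum(axis=(0, 1))
        gcols = g @ self.w.T                     # (b, length, k*c)
        gxp = np.zeros((b, length + 2 * pad, c), dtype=g.dtype)
        for i in range(k):
            gxp[:, i:i + length, :] += gcols[:, :, i * c:(i + 1) * c]
        return gxp[:, pad:pad + length, :]

    def grads(self):
        return [self.gw, self.gb]


class MaxPool1D:
    def __init__(self, size=2):
        self.size = size

    def params(self):
        return []

    def forward(self, x, train):
        b, length, c = x.shape
        s = self.size
        lout = length // s
        xv = x[:, :lout * s, :].reshape(b, lout, s, c)
        self._arg = xv.argmax(axis=2)
        self._in_shape = x.shape
        return xv.max(axis=2)

    def backward(self, g):
        b, length, c = self._in_shape
        s = self.size
        lout = length // s
        gx = np.zeros((b, lout, s, c), dtype=g.dtype)
        bi, li, ci = np.ogrid[:b, :lout, :c]
        gx[bi, li, self._arg, ci] = g
        gx = gx.reshape(b, lout * s, c)
        if lout * s < length:
            gx = np.pad(gx, ((0, 0), (0, length - lout * s), (0, 0)))
        return gx

    def grads(self):
        return []


class SmoothConv:
    """Single smoothing filter applied across the output spectrum.

    Same-length output via edge-replicated padding; trained jointly with the
    rest of the network.
    """

    def __init__(self, length, kernel, rng):
        self.kernel = kernel
        # initialise near-identity so training starts from the unsmoothed net
        w = np.zeros(kernel, dtype=np.float32)
        w[kernel // 2] = 1.0
        self.w = w + 0.01 * rng.standard_normal(kernel).astype(np.float32)
        self.b = np.zeros(1, dtype=np.float32)
        pad = kernel // 2
        self._idx = np.clip(np.arange(length)[:, None]
                            + np.arange(kernel)[None, :] - pad, 0, length - 1)

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        self._xg = x[:, self._idx]               # (b, length, kernel)
        return self._xg @ self.w + self.b

    def backward(self, g):
        self.gw = np.tensordot(g, self._xg, axes=([0, 1], [0, 1]))
        self.gb = np.array([g.sum()], dtype=np.float32)
        gx = np.zeros((g.shape[0], self._idx.shape[0]), dtype=g.dtype)
        contrib = g[:, :, None] * self.w[None, None, :]
        np.add.at(gx, (slice(None), self._idx), contrib)
        return gx

    def grads(self):
        return [self.gw, self.gb]


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class Network:
    """Plain sequential network trained with MSE loss."""

    def __init__(self, layers, cfg: TrainConfig):
        self.layers = layers
        self.cfg = cfg

    def _forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        out = []
        for start in range(0, x.shape[0], 4096):
            out.append(self._forward(x[start:start + 4096], train=False))
        return np.concatenate(out).astype(np.float64)

    def init_output_bias(self, y):
        """Start the head at the target mean (faster, scale-aware start)."""
        for layer in reversed(self.layers):
            if isinstance(layer, Dense):
                layer.b[...] = np.mean(y, axis=0).astype(np.float32)
                break
        return self

    def fit(self, x, y, verbose=False):
        x = np.asarray(x, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed)
        params = [p for layer in self.layers for p in layer.params()]
        opt = Adam(params)
        n = x.shape[0]
        history = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            lr = cfg.lr_at(epoch)
            total = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                xb, yb = x[idx], y[idx]
                out = self._forward(xb, train=True)
                resid = out - yb
                loss = float(np.mean(resid ** 2))
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}")
                total += loss * len(idx)
                g = (2.0 / resid.size) * resid
                for layer in reversed(self.layers):
                    g = layer.backward(g)
                grads = [gr for layer in self.layers for gr in layer.grads()]
                opt.step(grads, lr, cfg.grad_clip)
            history.append(total / n)
            if verbose and (epoch % 25 == 0 or epoch == cfg.epochs - 1):
                print(f"epoch {epoch:3d}  mse {history[-1]:.3e}")
        self.history = history
        return self

    # -- persistence --------------------------------------------------------

    def state_arrays(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def save(self, path, **meta):
        arrays = {f"p{i}": p for i, p in enumerate(self.state_arrays())}
        np.savez_compressed(path, n_arrays=len(arrays), **arrays, **meta)

    def load_state(self, path):
        with np.load(path) as z:
            arrays = [z[f"p{i}"] for i in range(int(z["n_arrays"]))]
        for p, a in zip(self.state_arrays(), arrays):
            p[...] = a
        return self
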