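"""Minimal NumPy neural-network layers with hand-written gradients.

Every layer exposes ``forward(x, train=...)`` and ``backward(grad)``; the
forward pass caches whatever the backward pass needs.  Parameters and their
gradients live in per-layer dicts keyed by name so optimizers and
checkpoints can walk them generically via :meth:`Layer.named_params`.

Conventions: dense inputs are (batch, features); convolutional inputs are
(batch, channels, length).  All arrays are float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Layer", "Dense", "Conv1d", "BatchNorm1d", "ReLU", "Tanh", "Adam"]


class Layer:
    """Base class; subclasses populate ``params`` and ``grads`` dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def named_params(self, prefix: str = ""):
        for k in self.params:
            yield f"{prefix}{k}", self.params[k], self.grads

    def state_arrays(self, prefix: str = "") -> dict[str, np.ndarray]:
        """All persistent arrays (parameters + buffers) for checkpointing."""
        return {f"{prefix}{k}": v for k, v in self.params.items()}

    def load_state(self, arrays: dict[str, np.ndarray], prefix: str = "") -> None:
        for k in self.params:
            self.params[k][...] = arrays[f"{prefix}{k}"]


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense(Layer):
    """Affine map y = x W^T + b with W of shape (out, in)."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["W"] = glorot_uniform(rng, (d_out, d_in), d_in, d_out)
        self.params["b"] = np.zeros(d_out)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads["W"] += grad.T @ self._x
        self.grads["b"] += grad.sum(axis=0)
        return grad @ self.params["W"]


class Conv1d(Layer):
    """1-D convolution (cross-correlation) over (batch, channels, length).

    Output length is ``(L + 2*padding - kernel) // stride + 1``.  The
    forward loops over the (small) kernel taps only, so each tap is a single
    einsum over the batch.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        stride: int,
        padding: int,
        rng: np.random.Generator,
        bias: bool = True,
    ) -> None:
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride, self.padding = kernel, stride, padding
        fan_in, fan_out = c_in * kernel, c_out * kernel
        self.params["W"] = glorot_uniform(rng, (c_out, c_in, kernel), fan_in, fan_out)
        self.has_bias = bias
        if bias:
            self.params["b"] = np.zeros(c_out)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def out_length(self, L: int) -> int:
        Lo = (L + 2 * self.padding - self.kernel) // self.stride + 1
        if Lo < 1:
            raise ValueError(
                f"input length {L} too short for kernel={self.kernel} "
                f"stride={self.stride} padding={self.padding}"
            )
        return Lo

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, C, L = x.shape
        if C != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {C}")
        Lo = self.out_length(L)
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p))) if p else x
        self._xp, self._Lo, self._Lpad = xp, Lo, L + 2 * p
        W = self.params["W"]
        out = np.zeros((B, self.c_out, Lo))
        for t in range(self.kernel):
            xs = xp[:, :, t : t + self.stride * Lo : self.stride]
            out += np.einsum("oc,bcl->bol", W[:, :, t], xs, optimize=True)
        if self.has_bias:
            out += self.params["b"][None, :, None]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp, Lo = self._xp, self._Lo
        W = self.params["W"]
        gxp = np.zeros_like(xp)
        for t in range(self.kernel):
            sl = slice(t, t + self.stride * Lo, self.stride)
            xs = xp[:, :, sl]
            self.grads["W"][:, :, t] += np.einsum("bol,bcl->oc", grad, xs, optimize=True)
            gxp[:, :, sl] += np.einsum("oc,bol->bcl", W[:, :, t], grad, optimize=True)
        if self.has_bias:
            self.grads["b"] += grad.sum(axis=(0, 2))
        p = self.padding
        return gxp[:, :, p : gxp.shape[2] - p] if p else gxp


class BatchNorm1d(Layer):
    """Batch normalization over (batch, channels, length) per channel.

    Train mode normalizes with batch statistics and updates exponential
    running estimates (momentum 0.1); eval mode uses the running estimates.
    Running buffers are persisted but carry no gradient.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            n = x.shape[0] * x.shape[2]
            unbiased = var * n / max(n - 1, 1)
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._xhat, self._inv, self._train, self._n = xhat, inv, train, x.shape[0] * x.shape[2]
        return self.params["gamma"][None, :, None] * xhat + self.params["beta"][None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        self.grads["gamma"] += (grad * xhat).sum(axis=(0, 2))
        self.grads["beta"] += grad.sum(axis=(0, 2))
        g = grad * self.params["gamma"][None, :, None]
        if not self._train:
            return g * inv[None, :, None]
        n = self._n
        gsum = g.sum(axis=(0, 2))[None, :, None]
        gxsum = (g * xhat).sum(axis=(0, 2))[None, :, None]
        return inv[None, :, None] * (g - gsum / n - xhat * gxsum / n)

    def state_arrays(self, prefix: str = "") -> dict[str, np.ndarray]:
        d = super().state_arrays(prefix)
        d[f"{prefix}running_mean"] = self.running_mean
        d[f"{prefix}running_var"] = self.running_var
        return d

    def load_state(self, arrays: dict[str, np.ndarray], prefix: str = "") -> None:
        super().load_state(arrays, prefix)
        self.running_mean = np.array(arrays[f"{prefix}running_mean"])
        self.running_var = np.array(arrays[f"{prefix}running_var"])


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Tanh(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * (1.0 - self._y**2)


class Adam:
    """Adam optimizer over the parameters of an iterable of layers."""

    def __init__(self, layers, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8) -> None:
        self.entries = []
        for layer in layers:
            for key, p in layer.params.items():
                self.entries.append((p, layer.grads, key))
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p) for p, _, _ in self.entries]
        self.v = [np.zeros_like(p) for p, _, _ in self.entries]
        self.t = 0

    def zero_grad(self) -> None:
        for _, grads, key in self.entries:
            grads[key][...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, (p, grads, key) in enumerate(self.entries):
            g = grads[key]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
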