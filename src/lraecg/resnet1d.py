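"""1-D ResNet-18 classifier head for autoencoder latents.

Each latent vector is treated as a single-channel sequence.  The stem maps
it through two convolutions (1→3 and 3→64 channels, kernel 3, stride 3,
padding 0) followed by batch norm and ReLU; four residual stages with
channel widths (64, 128, 256, 512) and two basic blocks each produce the
features; global average pooling and a fully connected layer yield the
four class scores.

A basic block's inner path is conv→BN→ReLU→conv→BN→ReLU (kernel 3,
stride 1, padding 1, except the first conv of a downsampling block which
uses stride 2), and the block output is ``F(x) + shortcut(x)`` — the ReLU
sits at the end of the inner path, before the addition.  Stage entries
2–4 halve the length with stride 2 and project the shortcut with a 1×1
convolution + BN; ``no_downsample=True`` keeps every block at stride 1
with identity shortcuts wherever channel counts allow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, BatchNorm1d, Conv1d, Dense, Layer, ReLU

__all__ = ["ClassifierConfig", "ResBlock", "ResNet1D", "relu", "softmax_logits"]

STAGE_CHANNELS = (64, 128, 256, 512)


def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise max(x, 0); zero maps to zero."""
    return np.maximum(np.asarray(x, dtype=float), 0.0)


def softmax_logits(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class ClassifierConfig:
    in_length: int = 64
    n_classes: int = 4
    seed: int = 0
    no_downsample: bool = False
    learning_rate: float = 1e-3
    batch_size: int = 64

    def stem_lengths(self) -> tuple[int, int]:
        l1 = (self.in_length - 3) // 3 + 1
        l2 = (l1 - 3) // 3 + 1
        if self.in_length < 3 or l1 < 3 or l2 < 1:
            raise ValueError(
                f"in_length={self.in_length} too short for the two stride-3 stem convolutions"
            )
        return l1, l2


class ResBlock(Layer):
    """Basic residual block: out = (conv→BN→ReLU→conv→BN→ReLU)(x) + shortcut(x)."""

    def __init__(self, c_in: int, c_out: int, stride: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.conv_a = Conv1d(c_in, c_out, 3, stride, 1, rng)
        self.bn_a = BatchNorm1d(c_out)
        self.relu_a = ReLU()
        self.conv_b = Conv1d(c_out, c_out, 3, 1, 1, rng)
        self.bn_b = BatchNorm1d(c_out)
        self.relu_b = ReLU()
        if stride != 1 or c_in != c_out:
            self.proj: Conv1d | None = Conv1d(c_in, c_out, 1, stride, 0, rng)
            self.proj_bn: BatchNorm1d | None = BatchNorm1d(c_out)
        else:
            self.proj = None
            self.proj_bn = None

    @property
    def sublayers(self) -> list[Layer]:
        layers = [self.conv_a, self.bn_a, self.conv_b, self.bn_b]
        if self.proj is not None:
            layers += [self.proj, self.proj_bn]
        return layers

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = self.relu_a.forward(self.bn_a.forward(self.conv_a.forward(x), train))
        h = self.relu_b.forward(self.bn_b.forward(self.conv_b.forward(h), train))
        if self.proj is not None:
            sc = self.proj_bn.forward(self.proj.forward(x), train)
        else:
            sc = x
        return h + sc

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.conv_b.backward(self.bn_b.backward(self.relu_b.backward(grad)))
        g = self.conv_a.backward(self.bn_a.backward(self.relu_a.backward(g)))
        if self.proj is not None:
            g = g + self.proj.backward(self.proj_bn.backward(grad))
        else:
            g = g + grad
        return g


@dataclass
class ClassifierOutputs:
    """Stem features, mid-stack features and class scores of one forward pass."""

    f1: np.ndarray
    f2: np.ndarray
    logits: np.ndarray

    @property
    def probabilities(self) -> np.ndarray:
        return softmax_logits(self.logits)


class ResNet1D:
    """The full classifier; parameters are initialized from ``config.seed``."""

    def __init__(self, config: ClassifierConfig) -> None:
        config.stem_lengths()  # validate geometry at build time
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.conv1 = Conv1d(1, 3, 3, 3, 0, rng)
        self.conv2 = Conv1d(3, STAGE_CHANNELS[0], 3, 3, 0, rng)
        self.stem_bn = BatchNorm1d(STAGE_CHANNELS[0])
        self.stem_relu = ReLU()
        self.blocks: list[ResBlock] = []
        c_prev = STAGE_CHANNELS[0]
        for si, c in enumerate(STAGE_CHANNELS):
            for bi in range(2):
                stride = 2 if (si > 0 and bi == 0 and not config.no_downsample) else 1
                self.blocks.append(ResBlock(c_prev, c, stride, rng))
                c_prev = c
        self.fc = Dense(STAGE_CHANNELS[-1], config.n_classes, rng)

    # -- plumbing ---------------------------------------------------------
    @property
    def layers(self) -> list[Layer]:
        out: list[Layer] = [self.conv1, self.conv2, self.stem_bn]
        for b in self.blocks:
            out.extend(b.sublayers)
        out.append(self.fc)
        return out

    def n_parameters(self) -> int:
        return sum(int(np.prod(p.shape)) for l in self.layers for p in l.params.values())

    def make_optimizer(self) -> Adam:
        return Adam(self.layers, lr=self.config.learning_rate)

    def state_arrays(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, l in enumerate(self.layers):
            out.update(l.state_arrays(prefix=f"layer{i:02d}."))
        return out

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        for i, l in enumerate(self.layers):
            l.load_state(arrays, prefix=f"layer{i:02d}.")

    # -- forward / backward ----------------------------------------------
    def forward(self, latents: np.ndarray, train: bool = False) -> ClassifierOutputs:
        """Classify a batch of latent vectors (n, in_length)."""
        X = np.asarray(latents, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.config.in_length:
            raise ValueError(f"expected (n, {self.config.in_length}) latents, got {X.shape}")
        h = X[:, None, :]  # 1-channel sequences
        h = self.conv2.forward(self.conv1.forward(h))
        f1 = self.stem_bn.forward(h, train)
        h = self.stem_relu.forward(f1)
        for b in self.blocks[:4]:
            h = b.forward(h, train)
        f2 = h
        for b in self.blocks[4:]:
            h = b.forward(h, train)
        pooled = h.mean(axis=2)
        self._pool_len = h.shape[2]
        logits = self.fc.forward(pooled)
        return ClassifierOutputs(f1=f1, f2=f2, logits=logits)

    def backward(self, grad_logits: np.ndarray) -> np.ndarray:
        """Accumulate parameter gradients; returns dLoss/d(latents)."""
        g = self.fc.backward(grad_logits)
        g = np.repeat(g[:, :, None], self._pool_len, axis=2) / self._pool_len
        for b in reversed(self.blocks[4:]):
            g = b.backward(g)
        for b in reversed(self.blocks[:4]):
            g = b.backward(g)
        g = self.stem_bn.backward(self.stem_relu.backward(g))
        g = self.conv1.backward(self.conv2.backward(g))
        return g[:, 0, :]

    # -- training ---------------------------------------------------------
    def train_epochs(
        self,
        latents: np.ndarray,
        labels: np.ndarray,
        epochs: int,
        rng: np.random.Generator,
        loss: str = "cross_entropy",
    ) -> list[float]:
        """Mini-batch Adam training; returns per-epoch mean training loss.

        ``loss`` is ``cross_entropy`` (softmax + log loss, the default) or
        ``mse_one_hot`` (squared error against one-hot targets).
        """
        X = np.asarray(latents, dtype=float)
        y = np.asarray(labels, dtype=int)
        opt = self.make_optimizer()
        n = X.shape[0]
        bs = min(self.config.batch_size, n)
        history: list[float] = []
        eye = np.eye(self.config.n_classes)
        for _ in range(epochs):
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                xb, yb = X[idx], y[idx]
                out = self.forward(xb, train=True)
                probs = softmax_logits(out.logits)
                onehot = eye[yb]
                if loss == "cross_entropy":
                    batch_loss = -np.mean(np.log(probs[np.arange(len(yb)), yb] + 1e-12))
                    grad = (probs - onehot) / len(yb)
                elif loss == "mse_one_hot":
                    diff = probs - onehot
                    batch_loss = float(np.mean(diff**2))
                    # d/dlogits of mean((softmax(z) - t)^2)
                    inner = 2.0 * diff / diff.size
                    dot = (inner * probs).sum(axis=1, keepdims=True)
                    grad = probs * (inner - dot)
                else:
                    raise ValueError(f"unknown loss {loss!r}")
                if not np.isfinite(batch_loss):
                    raise FloatingPointError("non-finite classifier loss")
                opt.zero_grad()
                self.backward(grad)
                opt.step()
                total += batch_loss * len(yb)
            history.append(total / n)
        if epochs > 0:
            self.calibrate_batchnorm(X)
        return history

    def calibrate_batchnorm(self, latents: np.ndarray) -> None:
        """Recompute batch-norm running statistics under the final weights.

        The exponential running estimates collected *while* the weights were
        moving lag the statistics of the finished network; one train-mode
        pass over the (full) calibration set with momentum 1 replaces them
        with the exact population statistics, so eval-mode forward matches
        the distribution the network was actually trained into.
        """
        bns = [l for l in self.layers if isinstance(l, BatchNorm1d)]
        saved = [bn.momentum for bn in bns]
        for bn in bns:
            bn.momentum = 1.0
        try:
            self.forward(latents, train=True)
        finally:
            for bn, m in zip(bns, saved):
                bn.momentum = m

    def predict(self, latents: np.ndarray) -> np.ndarray:
        """Eval-mode argmax predictions (ties broken toward the lowest class)."""
        out = self.forward(latents, train=False)
        return np.argmax(out.logits, axis=1)
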