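"""LRA-weighted autoencoder for ECG feature extraction.

The encoder has three dense tanh layers; before each one, the current
activations are multiplied by their own low-rank dimension-attention matrix:

    O1 = tanh(W1 (X  A(X))  + b1)
    O2 = tanh(W2 (O1 A(O1)) + b2)
    O3 = tanh(W3 (O2 A(O2)) + b3)

where ``A(.)`` is :func:`lraecg.attention.lra_weights` recomputed on that
layer's input at every forward pass.  The decoder maps the latent back:
``O4 = tanh(W4 O3 + b4)``, ``O5 = act(W5 O4 + b5)`` with a tanh (default) or
linear final activation.

Gradient isolation
------------------
The attention matrices participate in the forward value only.  During
backpropagation each ``A`` is treated as a constant: the gradient of
``X A`` with respect to ``X`` is taken as ``G A^T`` and nothing flows into
the SVD that produced ``A``.  With hand-written gradients this is the
natural (and here, contractual) behaviour; spatial weights shape the signal
but are never themselves updated by the reconstruction loss.

Because the final tanh bounds reconstructions in (−1, 1) while Z-scored
beats routinely exceed that range, :func:`pretrain_autoencoder` affinely
maps the training matrix into [−0.95, 0.95] (per dataset, inverse stored in
the returned state) before minimizing reconstruction MSE.  A ``linear``
final activation removes the need for the mapping but is not the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attention import lra_weights
from .nn import glorot_uniform

__all__ = [
    "AutoencoderConfig",
    "AutoencoderState",
    "TrainTrace",
    "apply_lra_weighting",
    "init_state",
    "encode",
    "decode",
    "pretrain_autoencoder",
    "reconstruction_mse",
]

TANH_RANGE = 0.95  # target half-range of the affine input mapping


@dataclass
class AutoencoderConfig:
    input_dim: int = 250
    encoder_dims: tuple[int, int, int] = (128, 96, 64)
    decoder_dims: tuple[int, int] = (128, 250)
    learning_rate: float = 1e-3
    epochs: int = 200
    seed: int = 0
    final_activation: str = "tanh"  # "tanh" | "linear"
    batch_size: int | None = None  # None -> full batch

    def __post_init__(self) -> None:
        if self.input_dim < 1 or any(d < 1 for d in self.encoder_dims) or any(
            d < 1 for d in self.decoder_dims
        ):
            raise ValueError("all layer dimensions must be >= 1")
        if len(self.encoder_dims) != 3 or len(self.decoder_dims) != 2:
            raise ValueError("expected 3 encoder dims and 2 decoder dims")
        if self.decoder_dims[-1] != self.input_dim:
            raise ValueError(
                f"decoder must end at input_dim={self.input_dim}, got {self.decoder_dims[-1]}"
            )
        if self.final_activation not in ("tanh", "linear"):
            raise ValueError(f"unknown final_activation {self.final_activation!r}")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass
class AutoencoderState:
    """Weights/biases of the five dense layers plus the input scaling map.

    ``scale``/``shift`` store the affine map u = scale*x + shift applied to
    inputs before reconstruction training (identity when not fitted).
    """

    weights: dict[str, np.ndarray]
    config: AutoencoderConfig
    scale: float = 1.0
    shift: float = 0.0

    def copy(self) -> "AutoencoderState":
        return AutoencoderState(
            weights={k: v.copy() for k, v in self.weights.items()},
            config=self.config,
            scale=self.scale,
            shift=self.shift,
        )


@dataclass
class TrainTrace:
    losses: list[float] = field(default_factory=list)
    epochs_run: int = 0
    seed: int = 0


@dataclass
class LayerOutputs:
    O1: np.ndarray
    O2: np.ndarray
    O3: np.ndarray
    O4: np.ndarray | None = None
    O5: np.ndarray | None = None


def apply_lra_weighting(X: np.ndarray) -> np.ndarray:
    """Weight the columns of X by its own dimension-attention matrix: X A(X)."""
    X = np.asarray(X, dtype=float)
    return X @ lra_weights(X)


def init_state(config: AutoencoderConfig) -> AutoencoderState:
    rng = np.random.default_rng(config.seed)
    dims = [config.input_dim, *config.encoder_dims, *config.decoder_dims]
    weights: dict[str, np.ndarray] = {}
    for i in range(5):
        d_in, d_out = dims[i], dims[i + 1]
        weights[f"W{i + 1}"] = glorot_uniform(rng, (d_out, d_in), d_in, d_out)
        weights[f"b{i + 1}"] = np.zeros(d_out)
    return AutoencoderState(weights=weights, config=config)


def _forward(X: np.ndarray, state: AutoencoderState, cache: dict | None = None) -> LayerOutputs:
    w = state.weights
    act_final = np.tanh if state.config.final_activation == "tanh" else (lambda v: v)
    ins, attns, pre = [], [], []
    h = X
    for i in range(3):
        A = lra_weights(h)
        hA = h @ A
        z = hA @ w[f"W{i + 1}"].T + w[f"b{i + 1}"]
        ins.append(hA)
        attns.append(A)
        pre.append(z)
        h = np.tanh(z)
        if i == 0:
            O1 = h
        elif i == 1:
            O2 = h
        else:
            O3 = h
    z4 = O3 @ w["W4"].T + w["b4"]
    O4 = np.tanh(z4)
    z5 = O4 @ w["W5"].T + w["b5"]
    O5 = act_final(z5)
    if cache is not None:
        cache.update(X=X, ins=ins, attns=attns, O=[O1, O2, O3, O4, O5], z5=z5)
    return LayerOutputs(O1=O1, O2=O2, O3=O3, O4=O4, O5=O5)


def encode(X: np.ndarray, state: AutoencoderState) -> LayerOutputs:
    """Run the three LRA-weighted encoder layers; O3 is the latent code."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != state.config.input_dim:
        raise ValueError(
            f"X must be n×{state.config.input_dim}, got {np.shape(X)}"
        )
    out = _forward_encoder_only(X, state)
    return out


def _forward_encoder_only(X: np.ndarray, state: AutoencoderState) -> LayerOutputs:
    w = state.weights
    h = X
    outs = []
    for i in range(3):
        h = np.tanh((h @ lra_weights(h)) @ w[f"W{i + 1}"].T + w[f"b{i + 1}"])
        outs.append(h)
    return LayerOutputs(O1=outs[0], O2=outs[1], O3=outs[2])


def decode(O3: np.ndarray, state: AutoencoderState) -> np.ndarray:
    """Run the two decoder layers back to the input dimension."""
    O3 = np.asarray(O3, dtype=float)
    if O3.ndim != 2 or O3.shape[1] != state.config.encoder_dims[2]:
        raise ValueError(
            f"O3 must be n×{state.config.encoder_dims[2]}, got {np.shape(O3)}"
        )
    w = state.weights
    O4 = np.tanh(O3 @ w["W4"].T + w["b4"])
    z5 = O4 @ w["W5"].T + w["b5"]
    return np.tanh(z5) if state.config.final_activation == "tanh" else z5


def reconstruct(X: np.ndarray, state: AutoencoderState) -> np.ndarray:
    return _forward(np.asarray(X, dtype=float), state).O5


def reconstruction_mse(X: np.ndarray, state: AutoencoderState, scaled: bool = True) -> float:
    """Mean squared reconstruction error on the (optionally pre-scaled) data."""
    X = np.asarray(X, dtype=float)
    U = state.scale * X + state.shift if scaled else X
    R = reconstruct(U, state)
    return float(np.mean((U - R) ** 2))


def _loss_and_grads(U: np.ndarray, state: AutoencoderState):
    """Reconstruction MSE and gradients w.r.t. every weight/bias.

    Attention matrices cached in the forward pass re-enter the backward pass
    only as constant linear maps (grad of ``h A`` w.r.t. ``h`` is ``g A^T``).
    """
    w = state.weights
    cache: dict = {}
    _forward(U, state, cache)
    O1, O2, O3, O4, O5 = cache["O"]
    n = U.size
    diff = O5 - U
    loss = float(np.mean(diff**2))
    grads = {k: np.zeros_like(v) for k, v in w.items()}

    g = 2.0 * diff / n  # dL/dO5
    if state.config.final_activation == "tanh":
        g = g * (1.0 - O5**2)  # dL/dz5
    grads["W5"] = g.T @ O4
    grads["b5"] = g.sum(axis=0)
    g = (g @ w["W5"]) * (1.0 - O4**2)  # dL/dz4
    grads["W4"] = g.T @ O3
    grads["b4"] = g.sum(axis=0)
    g = g @ w["W4"]  # dL/dO3
    for i in (2, 1, 0):
        Oi = cache["O"][i]
        g = g * (1.0 - Oi**2)  # dL/dz_{i+1}
        grads[f"W{i + 1}"] = g.T @ cache["ins"][i]
        grads[f"b{i + 1}"] = g.sum(axis=0)
        if i > 0:
            # through the constant attention map: d(h A)/dh -> g A^T
            g = (g @ w[f"W{i + 1}"]) @ cache["attns"][i].T
    return loss, grads


def encode_with_cache(X: np.ndarray, state: AutoencoderState):
    """Encoder forward retaining per-layer inputs/attentions for backprop."""
    w = state.weights
    h = np.asarray(X, dtype=float)
    ins, attns, outs = [], [], []
    for i in range(3):
        A = lra_weights(h)
        hA = h @ A
        ins.append(hA)
        attns.append(A)
        h = np.tanh(hA @ w[f"W{i + 1}"].T + w[f"b{i + 1}"])
        outs.append(h)
    return outs[2], {"ins": ins, "attns": attns, "outs": outs}


def encoder_backward(cache: dict, state: AutoencoderState, g_O3: np.ndarray) -> dict:
    """Gradients of a downstream loss w.r.t. the three encoder layers.

    ``g_O3`` is dL/dO3; attention matrices are constants, as everywhere.
    """
    w = state.weights
    grads = {}
    g = g_O3
    for i in (2, 1, 0):
        g = g * (1.0 - cache["outs"][i] ** 2)
        grads[f"W{i + 1}"] = g.T @ cache["ins"][i]
        grads[f"b{i + 1}"] = g.sum(axis=0)
        if i > 0:
            g = (g @ w[f"W{i + 1}"]) @ cache["attns"][i].T
    return grads


class _AdamState:
    def __init__(self, weights: dict[str, np.ndarray], lr: float) -> None:
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in weights.items()}
        self.v = {k: np.zeros_like(v) for k, v in weights.items()}
        self.t = 0

    def step(self, weights: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        c1, c2 = 1 - b1**self.t, 1 - b2**self.t
        for k, p in weights.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            p -= self.lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + eps)


def fit_input_scaling(X: np.ndarray) -> tuple[float, float]:
    """Affine map sending [min(X), max(X)] onto [-TANH_RANGE, TANH_RANGE]."""
    lo, hi = float(X.min()), float(X.max())
    if hi == lo:
        return 1.0, -lo  # degenerate constant data -> map to 0
    scale = 2.0 * TANH_RANGE / (hi - lo)
    shift = -TANH_RANGE - scale * lo
    return scale, shift


def pretrain_autoencoder(
    X: np.ndarray, config: AutoencoderConfig
) -> tuple[AutoencoderState, TrainTrace]:
    """Train the autoencoder to reconstruct its input with Adam + MSE.

    ``X`` is an (n, d) matrix of fixed-length (typically Z-scored) segments.
    Runs ``config.epochs`` epochs of full-batch Adam (mini-batches when
    ``config.batch_size`` is set); the per-epoch loss is the full-data MSE
    after that epoch's update(s).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a non-empty n×d matrix")
    if X.shape[1] != config.input_dim:
        raise ValueError(f"segments have length {X.shape[1]}, config expects {config.input_dim}")
    state = init_state(config)
    if config.final_activation == "tanh":
        state.scale, state.shift = fit_input_scaling(X)
    U = state.scale * X + state.shift
    trace = TrainTrace(seed=config.seed)
    if config.epochs == 0:
        return state, trace
    opt = _AdamState(state.weights, config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    n = U.shape[0]
    bs = config.batch_size or n
    for _ in range(config.epochs):
        order = rng.permutation(n) if bs < n else np.arange(n)
        for start in range(0, n, bs):
            batch = U[order[start : start + bs]]
            loss, grads = _loss_and_grads(batch, state)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite reconstruction loss at epoch {trace.epochs_run}"
                )
            opt.step(state.weights, grads)
        epoch_loss = float(np.mean((U - reconstruct(U, state)) ** 2)) if bs < n else loss
        trace.losses.append(epoch_loss)
        trace.epochs_run += 1
    return state, trace
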