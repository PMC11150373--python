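"""End-to-end orchestration: data → LRA-autoencoder → 1D ResNet-18 → report.

``train_pipeline`` builds a beat dataset (synthetic by default, or loaded
from fixtures / WFDB records), splits it into stratified train/test parts,
pretrains the LRA-autoencoder on the training segments, trains the
classifier on the encoder latents, and evaluates on the held-out part.
Every stage is seeded, so (config, seed) fully determines the report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autoencoder import (
    AutoencoderConfig,
    AutoencoderState,
    TrainTrace,
    encode,
    pretrain_autoencoder,
)
from .ecg_io import BeatDataset, load_record, segment_beats
from .metrics import MetricsReport, class_metrics, confusion_matrix
from .resnet1d import ClassifierConfig, ResNet1D
from .synthetic import synth_beat_dataset

__all__ = ["RunConfig", "EvaluationReport", "train_pipeline", "evaluate", "stratified_split"]


@dataclass
class RunConfig:
    source: str = "synthetic"  # "synthetic" | "fixture" | "wfdb"
    data_path: str | None = None  # for fixture/wfdb sources
    n_per_class: int = 280
    d: int = 250
    window: tuple[int, int] = (100, 150)
    train_fraction: float = 5.0 / 7.0  # 280/class -> 200 train / 80 test
    seed: int = 42
    autoencoder: AutoencoderConfig | None = None
    classifier: ClassifierConfig | None = None
    classifier_epochs: int = 30
    classifier_loss: str = "cross_entropy"  # | "mse_one_hot"
    joint_training: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.autoencoder is None:
            self.autoencoder = AutoencoderConfig(input_dim=self.d, decoder_dims=(128, self.d), seed=self.seed)
        if self.classifier is None:
            self.classifier = ClassifierConfig(
                in_length=self.autoencoder.encoder_dims[-1], seed=self.seed
            )


@dataclass
class EvaluationReport:
    confusion: np.ndarray
    metrics: MetricsReport
    label_map: dict[int, str]
    seed: int
    autoencoder_trace: list[float] = field(default_factory=list)
    classifier_trace: list[float] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "label_map": {str(k): v for k, v in sorted(self.label_map.items())},
            "seed": self.seed,
            "metrics": self.metrics.as_dict(),
            "autoencoder_trace": [float(v) for v in self.autoencoder_trace],
            "classifier_trace": [float(v) for v in self.classifier_trace],
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), sort_keys=True, indent=2)

    def digest(self) -> str:
        """SHA-256 over the canonical JSON serialization."""
        return hashlib.sha256(self.to_json().encode()).hexdigest()

    def table(self) -> str:
        """Plain-text metric table, one column per class."""
        labels = [self.label_map[k] for k in sorted(self.label_map)]
        rows = [("Categories", *labels)]
        for name, attr in (("Precision", "precision"), ("Recall", "recall"), ("F1", "f1")):
            rows.append((name, *(f"{getattr(m, attr):.3f}" for m in self.metrics.per_class)))
        rows.append(("Acc", f"{self.metrics.accuracy:.3f}", *[""] * (len(labels) - 1)))
        widths = [max(len(r[i]) for r in rows) for i in range(len(rows[0]))]
        return "\n".join("  ".join(c.ljust(w) for c, w in zip(r, widths)).rstrip() for r in rows)


def stratified_split(
    labels: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded per-class split; returns (train_idx, test_idx)."""
    labels = np.asarray(labels)
    train, test = [], []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        idx = idx[rng.permutation(len(idx))]
        k = int(round(train_fraction * len(idx)))
        train.extend(idx[:k])
        test.extend(idx[k:])
    return np.sort(np.array(train, dtype=int)), np.sort(np.array(test, dtype=int))


def build_dataset(config: RunConfig) -> BeatDataset:
    if config.source == "synthetic":
        return synth_beat_dataset(config.n_per_class, d=config.d, seed=config.seed)
    if config.source in ("fixture", "wfdb"):
        if not config.data_path:
            raise ValueError(f"source {config.source!r} requires data_path")
        dialect = "csv_fixture" if config.source == "fixture" else "wfdb"
        record, anns = load_record(Path(config.data_path), dialect=dialect)
        ds = segment_beats(record, anns, window=config.window)
        if len(ds) == 0:
            raise ValueError(f"no usable beats in {config.data_path}")
        return ds
    raise ValueError(f"unknown source {config.source!r}")


def evaluate(
    ae_state: AutoencoderState, model: ResNet1D, dataset: BeatDataset, seed: int = 0
) -> EvaluationReport:
    """Eval-mode forward over every segment; confusion matrix + metrics."""
    if dataset.segments.shape[1] != ae_state.config.input_dim:
        raise ValueError(
            f"dataset d={dataset.segments.shape[1]} does not match "
            f"autoencoder input_dim={ae_state.config.input_dim}"
        )
    U = ae_state.scale * dataset.segments + ae_state.shift
    latents = encode(U, ae_state).O3
    preds = model.predict(latents)
    C = confusion_matrix(dataset.labels, preds, model.config.n_classes)
    return EvaluationReport(
        confusion=C, metrics=class_metrics(C), label_map=dict(dataset.label_map), seed=seed
    )


def _train_joint(
    model: ResNet1D,
    ae_state: AutoencoderState,
    U: np.ndarray,
    y: np.ndarray,
    config: RunConfig,
    rng: np.random.Generator,
) -> list[float]:
    from .autoencoder import _AdamState, encode_with_cache, encoder_backward

    opt_cls = model.make_optimizer()
    opt_enc = _AdamState(ae_state.weights, config.autoencoder.learning_rate)
    n = U.shape[0]
    bs = min(model.config.batch_size, n)
    eye = np.eye(model.config.n_classes)
    history: list[float] = []
    for _ in range(config.classifier_epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            O3, cache = encode_with_cache(U[idx], ae_state)
            out = model.forward(O3, train=True)
            probs = np.exp(out.logits - out.logits.max(axis=1, keepdims=True))
            probs /= probs.sum(axis=1, keepdims=True)
            yb = y[idx]
            loss = -np.mean(np.log(probs[np.arange(len(yb)), yb] + 1e-12))
            grad = (probs - eye[yb]) / len(yb)
            opt_cls.zero_grad()
            g_lat = model.backward(grad)
            enc_grads = encoder_backward(cache, ae_state, g_lat)
            zero = {k: np.zeros_like(v) for k, v in ae_state.weights.items()}
            zero.update(enc_grads)
            opt_enc.step(ae_state.weights, zero)
            opt_cls.step()
            total += loss * len(yb)
        history.append(total / n)
    if config.classifier_epochs > 0:
        O3, _ = encode_with_cache(U, ae_state)
        model.calibrate_batchnorm(O3)
    return history


def train_pipeline(
    config: RunConfig,
) -> tuple[AutoencoderState, ResNet1D, TrainTrace, EvaluationReport]:
    """Full staged run: pretrain the autoencoder, train the classifier, evaluate.

    With ``joint_training=True`` the encoder keeps learning during the
    classification stage: the classifier loss is backpropagated through the
    latents into the three encoder layers (attention matrices stay
    constant).  The default is purely staged.
    """
    dataset = build_dataset(config)
    if len(dataset) == 0:
        raise ValueError("dataset is empty after filtering")
    rng = np.random.default_rng(config.seed)
    train_idx, test_idx = stratified_split(dataset.labels, config.train_fraction, rng)
    Xtr, ytr = dataset.segments[train_idx], dataset.labels[train_idx]
    Xte, yte = dataset.segments[test_idx], dataset.labels[test_idx]

    ae_state, trace = pretrain_autoencoder(Xtr, config.autoencoder)
    Utr = ae_state.scale * Xtr + ae_state.shift

    model = ResNet1D(config.classifier)
    cls_rng = np.random.default_rng(config.seed + 10_000)
    if config.joint_training:
        cls_trace = _train_joint(model, ae_state, Utr, ytr, config, cls_rng)
    else:
        latents_tr = encode(Utr, ae_state).O3
        cls_trace = model.train_epochs(
            latents_tr, ytr, config.classifier_epochs, cls_rng, loss=config.classifier_loss
        )

    test_ds = BeatDataset(
        segments=Xte, labels=yte, label_map=dict(dataset.label_map),
        provenance=[dataset.provenance[i] for i in test_idx] if dataset.provenance else [],
    )
    report = evaluate(ae_state, model, test_ds, seed=config.seed)
    report.autoencoder_trace = list(trace.losses)
    report.classifier_trace = list(cls_trace)
    return ae_state, model, trace, report
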