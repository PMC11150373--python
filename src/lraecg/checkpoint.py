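"""Checkpoint archives: one ``.npz`` per model, key -> float64 array.

The autoencoder checkpoint stores its five weight/bias pairs, the input
scaling constants and the config (as a JSON string); the classifier
checkpoint stores every layer's parameters plus batch-norm running
statistics.  Round-trips are bit-exact (float64 in, float64 out).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .autoencoder import AutoencoderConfig, AutoencoderState
from .resnet1d import ClassifierConfig, ResNet1D

__all__ = [
    "save_autoencoder",
    "load_autoencoder",
    "save_classifier",
    "load_classifier",
]


def save_autoencoder(state: AutoencoderState, path) -> None:
    arrays = {f"weights/{k}": v for k, v in state.weights.items()}
    arrays["scaling"] = np.array([state.scale, state.shift])
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(state.config)).encode(), dtype=np.uint8
    )
    np.savez_compressed(Path(path), **arrays)


def load_autoencoder(path) -> AutoencoderState:
    with np.load(Path(path)) as z:
        cfg_raw = json.loads(bytes(z["config_json"]).decode())
        for key in ("encoder_dims", "decoder_dims"):
            cfg_raw[key] = tuple(cfg_raw[key])
        config = AutoencoderConfig(**cfg_raw)
        weights = {
            k.split("/", 1)[1]: np.array(z[k]) for k in z.files if k.startswith("weights/")
        }
        scale, shift = z["scaling"]
    return AutoencoderState(weights=weights, config=config, scale=float(scale), shift=float(shift))


def save_classifier(model: ResNet1D, path) -> None:
    arrays = dict(model.state_arrays())
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8
    )
    np.savez_compressed(Path(path), **arrays)


def load_classifier(path) -> ResNet1D:
    with np.load(Path(path)) as z:
        config = ClassifierConfig(**json.loads(bytes(z["config_json"]).decode()))
        model = ResNet1D(config)
        model.load_state({k: np.array(z[k]) for k in z.files if k != "config_json"})
    return model
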