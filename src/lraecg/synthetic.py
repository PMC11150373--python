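"""Seeded synthetic ECG beats and rhythm strips.

Beats are sums of Gaussian bumps — one per wave (P, Q, R, S, T) — whose
amplitudes, centers and widths are class-specific presets chosen so that
the four classes (N, L, R, V) are separable by morphology, the way their
clinical counterparts are.  Rhythm strips concatenate beats at RR
intervals drawn from a per-class jitter model (atrial-fibrillation-like
strips combine highly irregular RR with absent P waves; noisy strips bury
the signal under white noise with sub-0-dB SNR).

Everything is deterministic given a single integer seed.  The generator
is deliberately simple: white Gaussian noise only, no baseline wander, no
respiratory modulation, and no physiological validation — it provides the
statistical structure the classification pipeline assumes, not realism.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .ecg_io import (
    BeatAnnotation,
    BeatDataset,
    ECGRecord,
    MITBIH_LABEL_MAP,
    write_fixture_record,
    zscore,
)

__all__ = [
    "BeatMorphology",
    "RhythmSpec",
    "load_presets",
    "beat_preset",
    "rhythm_preset",
    "synth_beat",
    "synth_beat_dataset",
    "synth_rhythm_record",
    "write_fixture",
]

DEFAULT_R_FRACTION = 0.4  # R peak sits at sample round(0.4 * d), matching the
# default (pre=100, post=150) segmentation window for d=250


@dataclass
class BeatMorphology:
    class_label: str
    bumps: list[tuple[float, float, float]]  # (amplitude mV, center s, width s)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if any(w <= 0 for _, _, w in self.bumps):
            raise ValueError("bump widths must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class RhythmSpec:
    class_label: str
    duration_s: float
    fs: float
    mean_rr_s: float
    rr_jitter: dict
    beat: BeatMorphology
    noise_sd: float = 0.0
    p_amplitude_scale: float = 1.0


_PRESETS: dict | None = None


def load_presets() -> dict:
    global _PRESETS
    if _PRESETS is None:
        text = importlib.resources.files("lraecg").joinpath("presets.yaml").read_text()
        _PRESETS = yaml.safe_load(text)
    return _PRESETS


def beat_preset(label: str, noise_sd: float | None = None) -> BeatMorphology:
    spec = load_presets()["beats"][label]
    return BeatMorphology(
        class_label=label,
        bumps=[tuple(b) for b in spec["bumps"]],
        noise_sd=spec["noise_sd"] if noise_sd is None else noise_sd,
    )


def rhythm_preset(label: str) -> RhythmSpec:
    spec = load_presets()["rhythms"][label]
    return RhythmSpec(
        class_label=label,
        duration_s=spec["duration_s"],
        fs=spec["fs"],
        mean_rr_s=spec["mean_rr_s"],
        rr_jitter=dict(spec["rr_jitter"]),
        beat=beat_preset(spec["beat"], noise_sd=0.0),
        noise_sd=spec.get("noise_sd", 0.0),
        p_amplitude_scale=spec.get("p_amplitude_scale", 1.0),
    )


def _bumps_on_grid(bumps, t: np.ndarray) -> np.ndarray:
    out = np.zeros_like(t)
    for amp, center, width in bumps:
        out += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    return out


def synth_beat(
    morph: BeatMorphology,
    d: int,
    fs: float,
    rng: np.random.Generator,
    r_index: int | None = None,
) -> np.ndarray:
    """One beat of length d: the class's Gaussian bumps plus white noise.

    The R bump center (time 0 of the morphology) falls on sample
    ``r_index`` (default ``round(0.4 d)``).
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    r = int(round(DEFAULT_R_FRACTION * d)) if r_index is None else r_index
    t = (np.arange(d) - r) / fs
    clean = _bumps_on_grid(morph.bumps, t)
    if morph.noise_sd > 0:
        clean = clean + rng.normal(0.0, morph.noise_sd, size=d)
    return clean


def synth_beat_dataset(
    n_per_class: int,
    d: int = 250,
    seed: int = 0,
    fs: float = 360.0,
    noise_sd: float | None = None,
    normalization: str = "collection",
) -> BeatDataset:
    """A shuffled Z-scored dataset with n_per_class beats per class.

    ``normalization="collection"`` (default) standardizes the whole stacked
    collection with one mean/std, the synthetic analog of the pipeline's
    per-*record* Z-score: each beat keeps its offset relative to the
    collection, the way a beat cut from a standardized record does.
    ``"per_beat"`` standardizes every beat individually instead, which
    erases between-beat amplitude/offset information.
    """
    if n_per_class < 0:
        raise ValueError("n_per_class must be >= 0")
    if normalization not in ("collection", "per_beat"):
        raise ValueError(f"unknown normalization {normalization!r}")
    rng = np.random.default_rng(seed)
    segments, labels, prov = [], [], []
    for label_idx, symbol in MITBIH_LABEL_MAP.items():
        morph = beat_preset(symbol, noise_sd=noise_sd)
        for k in range(n_per_class):
            beat = synth_beat(morph, d, fs, rng)
            if normalization == "per_beat":
                beat = zscore(beat)
            segments.append(beat)
            labels.append(label_idx)
            prov.append(f"synthetic:{symbol}:{seed}:{k}")
    if not segments:
        return BeatDataset(
            segments=np.zeros((0, d)), labels=np.zeros(0, dtype=int),
            label_map=dict(MITBIH_LABEL_MAP),
        )
    stacked = np.vstack(segments)
    if normalization == "collection":
        stacked = zscore(stacked)
    order = rng.permutation(len(segments))
    return BeatDataset(
        segments=stacked[order],
        labels=np.asarray(labels)[order],
        label_map=dict(MITBIH_LABEL_MAP),
        provenance=[prov[i] for i in order],
    )


def synth_rhythm_record(
    spec: RhythmSpec, rng: np.random.Generator, record_id: str | None = None
) -> ECGRecord:
    """A rhythm strip assembled from beats at jittered RR intervals.

    The record's ``meta`` keeps the emitted RR list, R-peak indices and the
    clean (noise-free) component so RR variability and SNR are measurable
    post-conditions rather than intentions.
    """
    fs = spec.fs
    n = int(round(spec.duration_s * fs))
    t_axis = np.arange(n) / fs
    jm = spec.rr_jitter
    r_times: list[float] = []
    t = 0.4 * spec.mean_rr_s
    while t < spec.duration_s:
        r_times.append(t)
        if jm["model"] == "gaussian":
            rr = spec.mean_rr_s + rng.normal(0.0, jm["sd_s"])
        elif jm["model"] == "uniform":
            rr = rng.uniform(jm["low_s"], jm["high_s"])
        else:
            raise ValueError(f"unknown RR jitter model {jm['model']!r}")
        t += max(rr, 0.2)  # refractory floor
    bumps = [
        (amp * (spec.p_amplitude_scale if center < -0.1 else 1.0), center, width)
        for amp, center, width in spec.beat.bumps
    ]
    clean = np.zeros(n)
    for rt in r_times:
        clean += _bumps_on_grid(bumps, t_axis - rt)
    noise = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else np.zeros(n)
    rr_list = np.diff(r_times)
    rec = ECGRecord(
        signal=clean + noise,
        fs=fs,
        lead_names=["I"],
        record_id=record_id or f"synth-{spec.class_label}",
        meta={
            "class_label": spec.class_label,
            "rr_intervals_s": rr_list,
            "r_indices": np.round(np.asarray(r_times) * fs).astype(int),
            "clean": clean,
            "noise_sd": spec.noise_sd,
        },
    )
    return rec


def record_annotations(record: ECGRecord, symbol: str = "N") -> list[BeatAnnotation]:
    """Beat annotations at the generator's true R-peak indices."""
    idx = record.meta.get("r_indices")
    if idx is None:
        raise ValueError("record carries no generator R-peak metadata")
    return [BeatAnnotation(int(i), symbol) for i in idx if 0 <= i < record.n_samples]


def write_fixture(obj, path, annotations: list[BeatAnnotation] | None = None) -> None:
    """Write a record (csv_fixture pair) or a BeatDataset (segments+labels CSVs)."""
    path = Path(path)
    if isinstance(obj, ECGRecord):
        anns = annotations if annotations is not None else (
            record_annotations(obj) if "r_indices" in obj.meta else []
        )
        write_fixture_record(obj, anns, path)
    elif isinstance(obj, BeatDataset):
        path.mkdir(parents=True, exist_ok=True)
        np.savetxt(path / "segments.csv", obj.segments, delimiter=",")
        with open(path / "labels.csv", "w") as fh:
            fh.write("label,symbol,provenance\n")
            prov = obj.provenance or [""] * len(obj)
            for lab, p in zip(obj.labels, prov):
                fh.write(f"{lab},{obj.label_map[int(lab)]},{p}\n")
    else:
        raise TypeError(f"cannot write fixture for {type(obj).__name__}")
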