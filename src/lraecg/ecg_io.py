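"""ECG record I/O, Z-score normalization, and beat segmentation.

Two on-disk dialects are supported by :func:`load_record`:

``csv_fixture``
    A plain-text pair ``<id>.csv`` / ``<id>.ann.csv``.  The signal file
    starts with a versioned header comment carrying the sampling rate and
    lead names, then one row per sample: ``sample_index,<lead1>,...``.  The
    annotation file has rows ``sample_index,symbol``.  All indices 0-based.

``wfdb``
    The PhysioBank triple ``<record>.hea`` / ``.dat`` / ``.atr``.  The
    header and the format-212 / format-16 signal encodings and the MIT
    annotation byte stream are decoded by a small built-in reader (header
    gain/baseline are applied, so samples come back in physical units).

Coordinates are 0-based and windows half-open ``[start, end)`` throughout.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ECGRecord",
    "BeatAnnotation",
    "BeatDataset",
    "MITBIH_LABEL_MAP",
    "PHYSIONET2017_LABEL_MAP",
    "zscore",
    "segment_beats",
    "prepare_fixed_length",
    "load_record",
]

FIXTURE_HEADER = "# lraecg csv_fixture v1"

MITBIH_LABEL_MAP = {0: "N", 1: "L", 2: "R", 3: "V"}
PHYSIONET2017_LABEL_MAP = {0: "Noisy", 1: "N", 2: "AF", 3: "Other"}
TARGET_SYMBOLS = ("N", "L", "R", "V")


@dataclass
class ECGRecord:
    """One multi-lead record: ``signal`` has shape (n_leads, n_samples), mV."""

    signal: np.ndarray
    fs: float
    lead_names: list[str]
    record_id: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass(frozen=True)
class BeatAnnotation:
    sample_index: int
    symbol: str


@dataclass
class BeatDataset:
    """Fixed-length Z-scored segments with integer labels and provenance."""

    segments: np.ndarray  # (n, d)
    labels: np.ndarray  # (n,) ints
    label_map: dict[int, str]
    provenance: list[str] = field(default_factory=list)
    n_boundary_dropped: int = 0
    n_symbol_filtered: int = 0

    def __post_init__(self) -> None:
        self.segments = np.atleast_2d(np.asarray(self.segments, dtype=float))
        self.labels = np.asarray(self.labels, dtype=int)
        if self.segments.shape[0] != len(self.labels):
            raise ValueError(
                f"{self.segments.shape[0]} segments vs {len(self.labels)} labels"
            )

    def __len__(self) -> int:
        return len(self.labels)


def zscore(signal: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Standardize to zero mean and unit (population, ``ddof=0``) std.

    A constant signal has zero variance; it is mapped to all zeros with a
    warning rather than raising.
    """
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("cannot Z-score an empty signal")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    mu = x.mean()
    sd = x.std(ddof=ddof)
    if sd == 0:
        warnings.warn("constant signal: Z-score is degenerate, returning zeros", stacklevel=2)
        return np.zeros_like(x)
    return (x - mu) / sd


def segment_beats(
    record: ECGRecord,
    annotations: list[BeatAnnotation],
    window: tuple[int, int] = (100, 150),
    lead: int = 0,
    target_symbols: tuple[str, ...] = TARGET_SYMBOLS,
    label_map: dict[int, str] | None = None,
) -> BeatDataset:
    """Cut Z-scored beat windows ``[r-pre, r+post)`` around annotated R peaks.

    Annotations whose symbol is outside ``target_symbols`` are filtered;
    windows that leave the record are dropped and counted.  The whole lead
    is Z-scored once (per record) before cutting.
    """
    pre, post = window
    if pre < 0 or post < 0 or pre + post < 1:
        raise ValueError("window (pre, post) must be nonnegative with pre+post >= 1")
    label_map = label_map or dict(enumerate(target_symbols))
    sym_to_label = {v: k for k, v in label_map.items()}
    z = zscore(record.signal[lead])
    segments, labels, prov = [], [], []
    dropped = filtered = 0
    for ann in annotations:
        if ann.symbol not in target_symbols:
            filtered += 1
            continue
        start, end = ann.sample_index - pre, ann.sample_index + post
        if start < 0 or end > record.n_samples:
            dropped += 1
            continue
        segments.append(z[start:end])
        labels.append(sym_to_label[ann.symbol])
        prov.append(f"{record.record_id}@{ann.sample_index}")
    if not segments:
        warnings.warn(
            f"record {record.record_id}: no usable beats "
            f"({filtered} off-target symbols, {dropped} boundary drops)",
            stacklevel=2,
        )
        seg_arr = np.zeros((0, pre + post))
    else:
        seg_arr = np.vstack(segments)
    return BeatDataset(
        segments=seg_arr,
        labels=np.asarray(labels, dtype=int),
        label_map=label_map,
        provenance=prov,
        n_boundary_dropped=dropped,
        n_symbol_filtered=filtered,
    )


def prepare_fixed_length(record: ECGRecord, target_len: int = 9000, lead: int = 0) -> np.ndarray:
    """Z-score one lead, then truncate or zero-pad to exactly ``target_len``.

    Z-score statistics are computed on the raw signal *before* padding, so
    the padded tail is exactly zero.
    """
    if target_len < 1:
        raise ValueError("target_len must be >= 1")
    z = zscore(record.signal[lead])
    if len(z) >= target_len:
        return z[:target_len]
    out = np.zeros(target_len)
    out[: len(z)] = z
    return out


# --------------------------------------------------------------------------
# csv_fixture dialect
# --------------------------------------------------------------------------


def write_fixture_record(record: ECGRecord, annotations: list[BeatAnnotation], path) -> None:
    """Write the csv_fixture pair for one record under ``path/<record_id>``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    sig_file = path / f"{record.record_id}.csv"
    ann_file = path / f"{record.record_id}.ann.csv"
    leads = ",".join(record.lead_names)
    with open(sig_file, "w") as fh:
        fh.write(f"{FIXTURE_HEADER} fs={record.fs:g} leads={leads}\n")
        fh.write("sample_index," + leads + "\n")
        for i in range(record.n_samples):
            vals = ",".join(repr(float(v)) for v in record.signal[:, i])
            fh.write(f"{i},{vals}\n")
    with open(ann_file, "w") as fh:
        fh.write("sample_index,symbol\n")
        for ann in annotations:
            fh.write(f"{ann.sample_index},{ann.symbol}\n")


def _load_csv_fixture(path: Path) -> tuple[ECGRecord, list[BeatAnnotation]]:
    sig_file = path if path.suffix == ".csv" else path.with_suffix(".csv")
    record_id = sig_file.stem
    ann_file = sig_file.with_name(f"{record_id}.ann.csv")
    if not sig_file.exists():
        raise FileNotFoundError(f"missing fixture signal file {sig_file}")
    if not ann_file.exists():
        raise FileNotFoundError(f"missing fixture annotation file {ann_file}")
    with open(sig_file) as fh:
        header = fh.readline().strip()
        if not header.startswith(FIXTURE_HEADER):
            raise ValueError(f"{sig_file}: not a csv_fixture file (header {header!r})")
        fields = dict(tok.split("=", 1) for tok in header[len(FIXTURE_HEADER) :].split() if "=" in tok)
        fs = float(fields["fs"])
        lead_names = fields["leads"].split(",")
        fh.readline()  # column header
        rows = [line.strip().split(",") for line in fh if line.strip()]
    signal = np.array([[float(v) for v in row[1:]] for row in rows]).T
    annotations = []
    with open(ann_file) as fh:
        fh.readline()
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2 or not parts[0].lstrip("-").isdigit() or not parts[1]:
                raise ValueError(f"{ann_file}:{lineno}: malformed annotation row {line!r}")
            annotations.append(BeatAnnotation(int(parts[0]), parts[1]))
    return ECGRecord(signal, fs, lead_names, record_id), annotations


# --------------------------------------------------------------------------
# WFDB dialect (built-in minimal reader: .hea text, format 212/16 .dat,
# MIT annotation .atr)
# --------------------------------------------------------------------------

# MIT annotation codes for the beat types used here (standard WFDB table).
_ATR_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 34: "e", 38: "f",
}


def _read_hea(hea_path: Path):
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec_tokens = lines[0].split()
    record_id = rec_tokens[0].split("/")[0]
    n_sig = int(rec_tokens[1])
    fs = float(rec_tokens[2].split("/")[0]) if len(rec_tokens) > 2 else 250.0
    n_samples = int(rec_tokens[3]) if len(rec_tokens) > 3 else 0
    sig_specs = []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        fname, fmt = tok[0], tok[1].split("x")[0].split(":")[0].split("+")[0]
        gain, baseline = 200.0, 0
        if len(tok) > 2:
            g = tok[2]
            if "(" in g:
                g, b = g.split("(")
                baseline = int(b.rstrip(")").split(")")[0])
            g = g.split("/")[0]
            gain = float(g) if float(g) != 0 else 200.0
        adc_zero = int(tok[4]) if len(tok) > 4 else 0
        if "(" not in (tok[2] if len(tok) > 2 else ""):
            baseline = adc_zero
        lead = tok[8] if len(tok) > 8 else f"lead{len(sig_specs)}"
        sig_specs.append(dict(fname=fname, fmt=int(fmt), gain=gain, baseline=baseline, lead=lead))
    return record_id, n_sig, fs, n_samples, sig_specs


def _decode_212(raw: bytes, n_values: int) -> np.ndarray:
    b = np.frombuffer(raw, dtype=np.uint8)
    n_pairs = (n_values + 1) // 2
    b = b[: 3 * n_pairs]
    b0, b1, b2 = b[0::3].astype(np.int32), b[1::3].astype(np.int32), b[2::3].astype(np.int32)
    first = ((b1 & 0x0F) << 8) | b0
    second = ((b1 & 0xF0) << 4) | b2
    first = np.where(first > 2047, first - 4096, first)
    second = np.where(second > 2047, second - 4096, second)
    out = np.empty(2 * len(first), dtype=np.int32)
    out[0::2] = first
    out[1::2] = second
    return out[:n_values]


def _read_dat(dat_path: Path, fmt: int, n_sig: int, n_samples: int) -> np.ndarray:
    raw = dat_path.read_bytes()
    if fmt == 212:
        vals = _decode_212(raw, n_sig * n_samples)
    elif fmt == 16:
        vals = np.frombuffer(raw, dtype="<i2").astype(np.int32)[: n_sig * n_samples]
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt}")
    return vals.reshape(-1, n_sig).T  # interleaved frames -> (n_sig, n_samples)


def _read_atr(atr_path: Path) -> list[BeatAnnotation]:
    raw = atr_path.read_bytes()
    anns: list[BeatAnnotation] = []
    t = 0
    i = 0
    while i + 1 < len(raw):
        (word,) = struct.unpack_from("<H", raw, i)
        i += 2
        code, delta = word >> 10, word & 0x3FF
        if word == 0:  # EOF
            break
        if code == 59:  # SKIP: next two words form a 32-bit time offset
            (high,) = struct.unpack_from("<H", raw, i)
            (low,) = struct.unpack_from("<H", raw, i + 2)
            t += (high << 16) | low
            i += 4
        elif code in (60, 61, 62):  # NUM / SUB / CHN modifiers: ignored
            continue
        elif code == 63:  # AUX: skip payload (padded to even length)
            i += delta + (delta & 1)
        else:
            t += delta
            anns.append(BeatAnnotation(t, _ATR_CODE_TO_SYMBOL.get(code, "?")))
    return anns


def _load_wfdb(path: Path) -> tuple[ECGRecord, list[BeatAnnotation]]:
    base = path.with_suffix("") if path.suffix in (".hea", ".dat", ".atr") else path
    hea = base.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"missing WFDB header {hea}")
    record_id, n_sig, fs, n_samples, specs = _read_hea(hea)
    dat = base.parent / specs[0]["fname"]
    if not dat.exists():
        raise FileNotFoundError(f"missing WFDB signal file {dat}")
    adc = _read_dat(dat, specs[0]["fmt"], n_sig, n_samples)
    signal = np.empty(adc.shape, dtype=float)
    for k, spec in enumerate(specs):
        signal[k] = (adc[k] - spec["baseline"]) / spec["gain"]
    atr = base.with_suffix(".atr")
    annotations = _read_atr(atr) if atr.exists() else []
    leads = [s["lead"] for s in specs]
    return ECGRecord(signal, fs, leads, record_id), annotations


def load_record(path, dialect: str = "csv_fixture") -> tuple[ECGRecord, list[BeatAnnotation]]:
    """Load a record and its beat annotations in the given dialect."""
    path = Path(path)
    if dialect == "csv_fixture":
        return _load_csv_fixture(path)
    if dialect == "wfdb":
        return _load_wfdb(path)
    raise ValueError(f"unknown dialect {dialect!r}")
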