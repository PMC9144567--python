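"""Differential-entropy band features and temporal-context assembly.

Each 30-s epoch of each electrode is band-pass filtered into a set of
canonical sleep EEG bands and summarized by its differential entropy
under a Gaussian assumption, DE = ½·ln(2πe·σ²) nats.  Per-epoch feature
matrices (electrodes × bands) are then stacked into short temporal
context blocks — the network classifies the final epoch of each block
from the block as a whole.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .io_edf import LabelSequence, RawRecording

__all__ = [
    "Band",
    "DEFAULT_BANDS",
    "EpochedRecording",
    "ContextSet",
    "epoch_signal",
    "band_filter",
    "differential_entropy",
    "feature_matrix",
    "extract_features",
    "zscore_features",
    "assemble_contexts",
    "save_features_tsv",
    "load_features_tsv",
]

#: Value reported for a zero-variance (flat) band signal, where the
#: Gaussian differential entropy diverges to -inf.
DE_FLOOR = -20.0


@dataclass(frozen=True)
class Band:
    """A named frequency interval in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.low < self.high):
            raise ValueError(f"invalid band {self.name}: [{self.low}, {self.high}]")


#: Standard sleep EEG bands.  Sigma (11-16 Hz) overlaps alpha/beta and
#: captures the spindle activity characteristic of N2.
DEFAULT_BANDS: tuple[Band, ...] = (
    Band("delta", 0.5, 4.0),
    Band("theta", 4.0, 8.0),
    Band("alpha", 8.0, 13.0),
    Band("sigma", 11.0, 16.0),
    Band("beta", 16.0, 30.0),
)


@dataclass
class EpochedRecording:
    """Fixed-length epochs cut from a continuous recording.

    ``epochs`` has shape (n_epochs, channels, samples_per_epoch); labels,
    when present, align one-to-one with epochs.
    """

    subject_id: str
    sampling_rate: float
    channel_names: list[str]
    epochs: np.ndarray
    epoch_seconds: float = 30.0
    labels: list[str] | None = None

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]


def epoch_signal(rec: RawRecording, epoch_seconds: float = 30.0,
                 labels: LabelSequence | None = None) -> EpochedRecording:
    """Cut a recording into consecutive epochs, dropping any remainder.

    If a label sequence is supplied it is aligned to the epochs; extra
    trailing labels (or epochs) are dropped to the common length.
    """
    samples = int(round(epoch_seconds * rec.sampling_rate))
    if samples > rec.n_samples:
        raise ValueError(
            f"record of {rec.n_samples} samples is shorter than one "
            f"{epoch_seconds}-s epoch ({samples} samples)")
    n = rec.n_samples // samples
    lab_list: list[str] | None = None
    if labels is not None:
        n = min(n, len(labels))
        lab_list = list(labels.labels[:n])
    cut = rec.signal[:, :n * samples]
    epochs = cut.reshape(rec.n_channels, n, samples).transpose(1, 0, 2)
    return EpochedRecording(rec.subject_id, rec.sampling_rate,
                            list(rec.channel_names), epochs.copy(),
                            epoch_seconds, lab_list)


def band_filter(x: np.ndarray, band: Band, rate: float,
                order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass of one epoch.

    A 4th-order design applied forward and backward (``sosfiltfilt``), so
    the effective magnitude response is squared and the phase is zero.
    """
    nyq = rate / 2.0
    if band.high >= nyq:
        raise ValueError(f"band {band.name} upper edge {band.high} Hz "
                         f">= Nyquist {nyq} Hz")
    sos = sps.butter(order, [band.low, band.high], btype="bandpass",
                     fs=rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=np.float64))


def differential_entropy(x: np.ndarray, floor: float = DE_FLOOR) -> float:
    """Gaussian differential entropy of a signal, ½·ln(2πe·Var(x)) nats.

    Uses the population variance.  A flat signal (zero variance) returns
    ``floor`` with a warning instead of -inf.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise ValueError("differential entropy needs at least 2 samples")
    var = float(np.var(x))
    if var <= 0.0:
        warnings.warn("zero-variance signal: differential entropy floored",
                      stacklevel=2)
        return floor
    return 0.5 * float(np.log(2.0 * np.pi * np.e * var))


def feature_matrix(epoch: np.ndarray, bands: tuple[Band, ...],
                   rate: float) -> np.ndarray:
    """Per-electrode, per-band DE features of one epoch.

    ``epoch`` has shape (channels, samples); the result has shape
    (channels, len(bands)) in nats.
    """
    epoch = np.asarray(epoch, dtype=np.float64)
    out = np.empty((epoch.shape[0], len(bands)))
    for fi, band in enumerate(bands):
        filtered = band_filter(epoch, band, rate)  # filtfilt along last axis
        var = filtered.var(axis=-1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            de = 0.5 * np.log(2.0 * np.pi * np.e * var)
        out[:, fi] = np.where(var > 0.0, de, DE_FLOOR)
    return out


def extract_features(epoched: EpochedRecording,
                     bands: tuple[Band, ...] = DEFAULT_BANDS) -> np.ndarray:
    """DE features for every epoch: shape (n_epochs, channels, n_bands)."""
    return np.stack([
        feature_matrix(epoched.epochs[i], bands, epoched.sampling_rate)
        for i in range(epoched.n_epochs)
    ])


def zscore_features(feats: np.ndarray) -> np.ndarray:
    """Z-score each (electrode, band) feature across a recording's epochs.

    Stabilizes scale differences between subjects and electrodes before
    the network; constant features are left centered at zero.
    """
    mean = feats.mean(axis=0, keepdims=True)
    std = feats.std(axis=0, keepdims=True)
    std = np.where(std > 0, std, 1.0)
    return (feats - mean) / std


@dataclass
class ContextSet:
    """Temporal-context feature blocks ready for the network.

    ``values`` has shape (n_contexts, electrodes, bands, Tn) with
    Tn = k+1; ``labels[i]`` is the stage of the final epoch of block i,
    and ``epoch_index[i]`` is that epoch's index in the recording.
    """

    values: np.ndarray
    labels: np.ndarray            # integer class ids
    epoch_index: np.ndarray
    k: int
    d: int
    class_names: tuple[str, ...] = ("W", "N1", "N2", "N3", "R")

    @property
    def n_contexts(self) -> int:
        return self.values.shape[0]

    @property
    def context_len(self) -> int:
        return self.k + 1


def assemble_contexts(feats: np.ndarray, labels: list[str] | np.ndarray,
                      k: int = 4, d: int = 1,
                      class_names: tuple[str, ...] = ("W", "N1", "N2", "N3", "R"),
                      ) -> ContextSet:
    """Stack per-epoch feature matrices into temporal context blocks.

    A context for epoch t collects epochs t-k·d, t-(k-1)·d, …, t along a
    new trailing axis and is labeled with epoch t's stage.  Epochs with
    t < k·d have no full context and are dropped, so the output holds
    max(0, n_epochs - k·d) contexts.
    """
    if k < 0 or d < 1:
        raise ValueError("need k >= 0 and d >= 1")
    feats = np.asarray(feats)
    labels = list(labels)
    if feats.shape[0] != len(labels):
        raise ValueError("feature/label length mismatch")
    n = feats.shape[0]
    span = k * d
    if span >= n:
        warnings.warn(f"context span k*d={span} >= {n} epochs: no contexts",
                      stacklevel=2)
        empty = np.empty((0, feats.shape[1], feats.shape[2], k + 1))
        return ContextSet(empty, np.empty(0, dtype=int),
                          np.empty(0, dtype=int), k, d, tuple(class_names))
    idx = np.arange(span, n)
    offsets = np.arange(-span, 1, d)  # k+1 offsets ending at 0
    blocks = feats[idx[:, None] + offsets[None, :]]  # (M, Tn, N, Fde)
    values = blocks.transpose(0, 2, 3, 1)            # (M, N, Fde, Tn)
    class_to_id = {c: i for i, c in enumerate(class_names)}
    y = np.array([class_to_id[labels[t]] for t in idx], dtype=int)
    return ContextSet(values, y, idx, k, d, tuple(class_names))


# ---------------------------------------------------------------------------
# feature cache (TSV + JSON sidecar)
# ---------------------------------------------------------------------------

def save_features_tsv(path: str | Path, feats: np.ndarray,
                      channel_names: list[str],
                      bands: tuple[Band, ...],
                      labels: list[str] | None = None,
                      meta: dict | None = None) -> Path:
    """Write per-epoch DE features as TSV with a JSON metadata sidecar."""
    path = Path(path)
    n_epochs, n_ch, n_bands = feats.shape
    cols = [f"{ch}:{b.name}" for ch in channel_names for b in bands]
    with open(path, "w") as fh:
        header = ["epoch"] + cols + (["label"] if labels is not None else [])
        fh.write("\t".join(header) + "\n")
        for e in range(n_epochs):
            row = [str(e)] + [f"{v:.6f}" for v in feats[e].ravel()]
            if labels is not None:
                row.append(labels[e])
            fh.write("\t".join(row) + "\n")
    sidecar = {
        "channel_names": list(channel_names),
        "bands": [{"name": b.name, "low": b.low, "high": b.high}
                  for b in bands],
    }
    sidecar.update(meta or {})
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2))
    return path


def load_features_tsv(path: str | Path) -> tuple[np.ndarray, list[str] | None, dict]:
    """Read a feature TSV back into (n_epochs, channels, bands) + labels."""
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    n_ch = len(meta["channel_names"])
    n_bands = len(meta["bands"])
    rows, labels = [], []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        has_label = header[-1] == "label"
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if has_label:
                labels.append(parts[-1])
                parts = parts[:-1]
            rows.append([float(v) for v in parts[1:]])
    feats = np.array(rows).reshape(len(rows), n_ch, n_bands)
    return feats, (labels if labels and has_label else None), meta
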