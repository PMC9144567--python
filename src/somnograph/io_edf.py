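"""EDF/EDF+ polysomnography I/O and hypnogram harmonization.

Reads multi-channel EEG from EDF/EDF+ files, reads hypnograms from either
EDF+ annotation tracks (duration-bearing stage events, sleep-EDF style) or
plain-text TSV files with one label per 30-s epoch (ISRUC style), maps
R&K stage vocabularies onto the five AASM classes, and trims long wake
stretches at the edges of a recording.

EDF reading is delegated to :mod:`mne`.  Writing uses a minimal 16-bit
EDF encoder implemented here, sufficient for EEG-only recordings with a
single sampling rate; round-trips through ``mne`` are covered by tests.
"""

from __future__ import annotations

import datetime
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "RawRecording",
    "LabelSequence",
    "RK_LABELS",
    "AASM_LABELS",
    "DEFAULT_ALIASES",
    "read_recording",
    "write_recording",
    "read_hypnogram",
    "write_hypnogram_tsv",
    "harmonize_labels",
    "trim_peripheral_wake",
]

RK_LABELS = ("W", "S1", "S2", "S3", "S4", "REM", "MOVEMENT", "UNKNOWN")
AASM_LABELS = ("W", "N1", "N2", "N3", "R")

#: R&K -> AASM merge: S3 and S4 collapse into N3; movement/unknown epochs
#: are discarded rather than scored.
_RK_TO_AASM = {"W": "W", "S1": "N1", "S2": "N2", "S3": "N3", "S4": "N3",
               "REM": "R"}
_DROPPED = {"MOVEMENT", "UNKNOWN"}

#: Case-insensitive alias table for the label strings found in public
#: hypnograms.  Extend via the ``aliases`` argument of the readers.
DEFAULT_ALIASES = {
    "sleep stage w": "W",
    "sleep stage 1": "S1",
    "sleep stage 2": "S2",
    "sleep stage 3": "S3",
    "sleep stage 4": "S4",
    "sleep stage r": "REM",
    "sleep stage rem": "REM",
    "sleep stage ?": "UNKNOWN",
    "movement time": "MOVEMENT",
    "wake": "W",
    "rem": "REM",
    "nrem1": "N1",
    "nrem2": "N2",
    "nrem3": "N3",
}


@dataclass
class RawRecording:
    """Continuous multi-channel EEG in microvolts.

    ``signal`` has shape (channels, samples); every channel shares one
    sampling rate.
    """

    subject_id: str
    sampling_rate: float
    channel_names: list[str]
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.signal.shape[0] != len(self.channel_names):
            raise ValueError("channel_names length must match signal rows")
        if self.signal.shape[0] < 1:
            raise ValueError("recording needs at least one channel")
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_seconds(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class LabelSequence:
    """Per-epoch sleep-stage labels under one scoring scheme."""

    scheme: str  # "RK" or "AASM"
    labels: list[str]
    epoch_seconds: float = 30.0

    def __post_init__(self) -> None:
        if self.scheme not in ("RK", "AASM"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        vocab = RK_LABELS if self.scheme == "RK" else AASM_LABELS
        bad = sorted(set(self.labels) - set(vocab))
        if bad:
            raise ValueError(f"labels not in {self.scheme} vocabulary: {bad}")

    def __len__(self) -> int:
        return len(self.labels)


def _canonical_label(raw: str, aliases: dict[str, str] | None) -> str:
    table = dict(DEFAULT_ALIASES)
    if aliases:
        table.update({k.lower(): v for k, v in aliases.items()})
    key = raw.strip().lower()
    if key in table:
        return table[key]
    upper = raw.strip().upper()
    if upper in RK_LABELS or upper in AASM_LABELS:
        return upper
    raise ValueError(f"unrecognized stage label {raw!r}")


# ---------------------------------------------------------------------------
# signal I/O
# ---------------------------------------------------------------------------

def read_recording(path: str | Path, channels: list[str] | None = None,
                   subject_id: str | None = None) -> RawRecording:
    """Read an EDF/EDF+ file into a :class:`RawRecording` (microvolts).

    ``channels`` selects and orders a subset of the recorded channels;
    by default all channels are returned in file order.
    """
    import mne  # deferred: heavy import, only needed for file I/O

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    available = list(raw.ch_names)
    if channels is None:
        channels = available
    missing = [c for c in channels if c not in available]
    if missing:
        raise KeyError(f"channels not in EDF header: {missing} "
                       f"(available: {available})")
    data = raw.get_data(picks=channels) * 1e6  # mne returns volts
    return RawRecording(
        subject_id=subject_id or path.stem,
        sampling_rate=float(raw.info["sfreq"]),
        channel_names=list(channels),
        signal=data,
    )


def write_recording(path: str | Path, rec: RawRecording) -> Path:
    """Write a recording as 16-bit EDF (one-second data records).

    Each channel is scaled to its own physical range, so the round-trip
    error is bounded by the 16-bit quantization step.  The total sample
    count must be a whole number of seconds.
    """
    path = Path(path)
    rate = rec.sampling_rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    rate = int(round(rate))
    if rec.n_samples % rate != 0:
        raise ValueError("signal length must be a whole number of seconds")
    n_records = rec.n_samples // rate
    n_sig = rec.n_channels

    def f(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            b = b[:width]
        return b.ljust(width)

    now = datetime.datetime(2000, 1, 1, 0, 0, 0)
    header = b"".join([
        f("0", 8),
        f(rec.subject_id, 80),
        f("Startdate 01-JAN-2000", 80),
        f(now.strftime("%d.%m.%y"), 8),
        f(now.strftime("%H.%M.%S"), 8),
        f(str(256 * (n_sig + 1)), 8),
        f("", 44),
        f(str(n_records), 8),
        f("1", 8),
        f(str(n_sig), 4),
    ])

    phys_max = np.maximum(np.abs(rec.signal).max(axis=1), 1e-3)
    dig_min, dig_max = -32768, 32767

    def sig_field(values: list[str], width: int) -> bytes:
        return b"".join(f(v, width) for v in values)

    names = [n for n in rec.channel_names]
    header += sig_field(names, 16)
    header += sig_field([""] * n_sig, 80)              # transducer
    header += sig_field(["uV"] * n_sig, 8)             # physical dimension
    header += sig_field([f"{-pm:.6g}"[:8] for pm in phys_max], 8)
    header += sig_field([f"{pm:.6g}"[:8] for pm in phys_max], 8)
    header += sig_field([str(dig_min)] * n_sig, 8)
    header += sig_field([str(dig_max)] * n_sig, 8)
    header += sig_field([""] * n_sig, 80)              # prefiltering
    header += sig_field([str(rate)] * n_sig, 8)        # samples per record
    header += sig_field([""] * n_sig, 32)

    # digitize with the reader's affine convention: decoders map digital d
    # to (d - dig_min)*gain + phys_min, i.e. (d + 0.5)*gain for symmetric
    # ranges, so center the quantizer to keep error within half an LSB
    gain = 2.0 * phys_max / (dig_max - dig_min)
    digital = np.round(rec.signal / gain[:, None] - 0.5)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            block = digital[:, r * rate:(r + 1) * rate]
            fh.write(block.tobytes())
    return path


# ---------------------------------------------------------------------------
# hypnogram I/O
# ---------------------------------------------------------------------------

def read_hypnogram(path: str | Path, scheme: str | None = None,
                   dialect: str | None = None,
                   epoch_seconds: float = 30.0,
                   aliases: dict[str, str] | None = None) -> LabelSequence:
    """Read a hypnogram from TSV or an EDF+ annotation track.

    ``dialect`` is ``"tsv"`` or ``"edf"``; by default it is inferred from
    the file extension.  ``scheme`` forces the output vocabulary check;
    if omitted, RK is assumed whenever any R&K-only label occurs.
    """
    path = Path(path)
    if dialect is None:
        dialect = "edf" if path.suffix.lower() in (".edf", ".rec") else "tsv"
    if dialect == "tsv":
        labels = _read_hypnogram_tsv(path, aliases)
    elif dialect == "edf":
        labels = _read_hypnogram_edf(path, epoch_seconds, aliases)
    else:
        raise ValueError(f"unknown hypnogram dialect {dialect!r}")
    if scheme is None:
        rk_only = set(RK_LABELS) - set(AASM_LABELS)
        scheme = "RK" if set(labels) & rk_only else "AASM"
    return LabelSequence(scheme=scheme, labels=labels,
                         epoch_seconds=epoch_seconds)


def _read_hypnogram_tsv(path: Path,
                        aliases: dict[str, str] | None) -> list[str]:
    rows: list[tuple[int, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() in ("epoch_index", "epoch"):
                continue  # header row
            if len(parts) == 1:
                rows.append((len(rows), parts[0]))
            else:
                rows.append((int(parts[0]), parts[1]))
    rows.sort(key=lambda r: r[0])
    if rows and [r[0] for r in rows] != list(range(len(rows))):
        raise ValueError(f"{path}: epoch indices are not contiguous from 0")
    return [_canonical_label(lab, aliases) for _, lab in rows]


def _read_hypnogram_edf(path: Path, epoch_seconds: float,
                        aliases: dict[str, str] | None) -> list[str]:
    import mne

    ann = mne.read_annotations(str(path))
    return events_to_epoch_labels(
        ann.onset, ann.duration, list(ann.description),
        epoch_seconds=epoch_seconds, aliases=aliases)


def events_to_epoch_labels(onsets, durations, descriptions,
                           epoch_seconds: float = 30.0,
                           aliases: dict[str, str] | None = None) -> list[str]:
    """Expand duration-bearing stage events into one label per epoch."""
    end = 0.0
    for onset, dur in zip(onsets, durations):
        end = max(end, float(onset) + float(dur))
    n_epochs = int(end // epoch_seconds)
    labels: list[str | None] = [None] * n_epochs
    for onset, dur, desc in zip(onsets, durations, descriptions):
        lab = _canonical_label(str(desc), aliases)
        first = int(round(float(onset) / epoch_seconds))
        last = int(round((float(onset) + float(dur)) / epoch_seconds))
        for e in range(first, min(last, n_epochs)):
            labels[e] = lab
    if any(l is None for l in labels):
        raise ValueError("annotation track leaves epochs unlabeled")
    return [l for l in labels if l is not None]


def write_hypnogram_tsv(path: str | Path, seq: LabelSequence) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("epoch_index\tlabel\n")
        for i, lab in enumerate(seq.labels):
            fh.write(f"{i}\t{lab}\n")
    return path


# ---------------------------------------------------------------------------
# label harmonization and trimming
# ---------------------------------------------------------------------------

def harmonize_labels(seq: LabelSequence) -> tuple[LabelSequence, list[int]]:
    """Map an R&K sequence onto the five AASM classes.

    S1/S2 become N1/N2, S3 and S4 merge into N3, REM becomes R; epochs
    scored as movement or unknown are removed.  Returns the harmonized
    sequence and the indices (into the input) of the epochs kept.  AASM
    input is returned unchanged with the full index list.
    """
    if seq.scheme == "AASM":
        return seq, list(range(len(seq)))
    out: list[str] = []
    kept: list[int] = []
    for i, lab in enumerate(seq.labels):
        if lab in _DROPPED:
            continue
        out.append(_RK_TO_AASM[lab])
        kept.append(i)
    return LabelSequence("AASM", out, seq.epoch_seconds), kept


@dataclass
class TrimResult:
    """Half-open epoch range kept after peripheral-wake trimming."""

    start: int
    stop: int
    all_wake: bool = False

    def indices(self) -> list[int]:
        return list(range(self.start, self.stop))

    def __len__(self) -> int:
        return self.stop - self.start


def trim_peripheral_wake(seq: LabelSequence,
                         margin_minutes: float = 30.0) -> TrimResult:
    """Keep the sleep period plus a wake margin on each side.

    The kept range spans from ``margin_minutes`` before the first
    non-wake epoch to the same margin after the last one, clamped to the
    record.  A record containing no sleep yields an empty range and a
    warning.
    """
    if seq.scheme != "AASM":
        raise ValueError("trim expects an AASM-harmonized sequence")
    non_wake = [i for i, lab in enumerate(seq.labels) if lab != "W"]
    if not non_wake:
        warnings.warn("recording contains no sleep epochs; nothing kept",
                      stacklevel=2)
        return TrimResult(0, 0, all_wake=True)
    margin_epochs = int(round(margin_minutes * 60.0 / seq.epoch_seconds))
    start = max(0, non_wake[0] - margin_epochs)
    stop = min(len(seq), non_wake[-1] + margin_epochs + 1)
    return TrimResult(start, stop)
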