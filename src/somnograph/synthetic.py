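"""Synthetic polysomnography: stage-labeled multi-channel EEG.

The simulator emulates the structure of public sleep datasets — 30-s
epochs at 100 or 200 Hz, a handful of EEG channels, five AASM stages —
without any biophysical detail.  A first-order Markov chain generates
the hypnogram (sleep is strongly autocorrelated, so context windows
carry usable label information), and each epoch is synthesized as a sum
of random-phase band-limited sinusoids whose band weights depend on the
stage, plus broadband Gaussian noise:

* W  — alpha + beta, low amplitude (relaxed/active wakefulness)
* N1 — theta-dominant
* N2 — sigma + theta (sigma stands in for spindle activity)
* N3 — delta-dominant, high amplitude (slow-wave sleep)
* R  — theta + beta at low amplitude (desynchronized, wake-like)

These profiles give well-separated differential-entropy signatures, so
end-to-end learning tests probe the network rather than the data.  All
randomness flows from ``SimSpec.seed``; equal specs reproduce equal
datasets bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .features import (Band, DEFAULT_BANDS, assemble_contexts,
                       extract_features, epoch_signal, zscore_features)
from .graph import load_montage
from .io_edf import (LabelSequence, RawRecording, write_hypnogram_tsv,
                     write_recording)
from .network import STAGES, contexts_to_input

__all__ = [
    "StageProfile",
    "SimSpec",
    "DEFAULT_PROFILES",
    "DEFAULT_TRANSITIONS",
    "stationary_distribution",
    "sample_hypnogram",
    "synth_epoch",
    "simulate_subject",
    "write_dataset",
    "simulate_feature_dataset",
]


@dataclass(frozen=True)
class StageProfile:
    """Spectral recipe of one sleep stage.

    ``band_weights`` gives relative oscillatory power per band name;
    ``amplitude`` is the target RMS of the oscillatory part in µV;
    ``noise_floor`` is the standard deviation of the additive white
    noise in µV.
    """

    band_weights: dict[str, float]
    amplitude: float
    noise_floor: float = 4.0

    def __post_init__(self) -> None:
        if not self.band_weights or all(w <= 0 for w in
                                        self.band_weights.values()):
            raise ValueError("profile needs at least one positive band weight")
        if any(w < 0 for w in self.band_weights.values()):
            raise ValueError("band weights must be non-negative")


DEFAULT_PROFILES: dict[str, StageProfile] = {
    "W":  StageProfile({"alpha": 0.6, "beta": 0.4}, amplitude=30.0),
    "N1": StageProfile({"theta": 1.0}, amplitude=40.0),
    "N2": StageProfile({"sigma": 0.5, "theta": 0.5}, amplitude=50.0),
    "N3": StageProfile({"delta": 1.0}, amplitude=75.0),
    "R":  StageProfile({"theta": 0.6, "beta": 0.4}, amplitude=20.0),
}

#: Row-stochastic stage transitions (order W, N1, N2, N3, R) encoding
#: realistic sleep continuity: N2/N3 are sticky, wake leads into N1, and
#: REM is entered only from N2.  The stationary mix is N2-heavy with N1
#: the scarcest sleep stage, mirroring real datasets.
DEFAULT_TRANSITIONS = np.array([
    [0.88, 0.10, 0.02, 0.00, 0.00],   # W
    [0.05, 0.60, 0.35, 0.00, 0.00],   # N1
    [0.02, 0.05, 0.80, 0.09, 0.04],   # N2
    [0.01, 0.00, 0.14, 0.85, 0.00],   # N3
    [0.03, 0.05, 0.07, 0.00, 0.85],   # R
])


@dataclass
class SimSpec:
    """Full description of a synthetic dataset."""

    n_subjects: int = 4
    epochs_per_subject: int = 200
    channels: list[str] = field(
        default_factory=lambda: list(load_montage("isruc6")[0]))
    rate: float = 100.0
    transitions: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRANSITIONS.copy())
    profiles: dict[str, StageProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES))
    sinusoids_per_band: int = 3
    epoch_seconds: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.transitions = np.asarray(self.transitions, dtype=float)
        if self.transitions.shape != (5, 5):
            raise ValueError("transition matrix must be 5x5")
        if not np.allclose(self.transitions.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")
        if (self.transitions < 0).any():
            raise ValueError("transition probabilities must be non-negative")
        missing = set(STAGES) - set(self.profiles)
        if missing:
            raise ValueError(f"profiles missing stages: {sorted(missing)}")

    # -- YAML round trip ----------------------------------------------------
    def to_yaml(self, path: str | Path) -> Path:
        doc = {
            "n_subjects": self.n_subjects,
            "epochs_per_subject": self.epochs_per_subject,
            "channels": list(self.channels),
            "rate": float(self.rate),
            "transitions": self.transitions.tolist(),
            "profiles": {s: asdict(p) for s, p in self.profiles.items()},
            "sinusoids_per_band": self.sinusoids_per_band,
            "epoch_seconds": self.epoch_seconds,
            "seed": self.seed,
        }
        path = Path(path)
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimSpec":
        doc = yaml.safe_load(Path(path).read_text())
        if "profiles" in doc:
            doc["profiles"] = {s: StageProfile(**p)
                               for s, p in doc["profiles"].items()}
        if "transitions" in doc:
            doc["transitions"] = np.asarray(doc["transitions"], dtype=float)
        return cls(**doc)


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    P = np.asarray(P, dtype=float)
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _subject_rng(spec: SimSpec, subject: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, subject, stream])


def sample_hypnogram(spec: SimSpec, subject: int = 0,
                     start_stage: str = "W") -> LabelSequence:
    """Markov-chain hypnogram over the five AASM stages."""
    rng = _subject_rng(spec, subject, 0)
    state = STAGES.index(start_stage)
    labels = []
    for _ in range(spec.epochs_per_subject):
        labels.append(STAGES[state])
        state = rng.choice(5, p=spec.transitions[state])
    return LabelSequence("AASM", labels, spec.epoch_seconds)


def synth_epoch(stage: str, spec: SimSpec,
                rng: np.random.Generator) -> np.ndarray:
    """One 30-s multi-channel epoch for a stage: (channels, samples) µV.

    Sinusoid frequencies are drawn per band and shared across channels;
    phases are channel-specific, so channels are correlated but not
    identical.  The oscillatory part is scaled to the profile's RMS
    amplitude, with per-band power proportional to the band weights.
    """
    profile = spec.profiles[stage]
    n_ch = len(spec.channels)
    samples = int(round(spec.epoch_seconds * spec.rate))
    t = np.arange(samples) / spec.rate
    band_by_name = {b.name: b for b in DEFAULT_BANDS}
    total_w = sum(profile.band_weights.values())
    nyq = spec.rate / 2.0
    signal = np.zeros((n_ch, samples))
    for name, weight in sorted(profile.band_weights.items()):
        if weight <= 0:
            continue
        band = band_by_name[name]
        hi = min(band.high, 0.95 * nyq)
        freqs = rng.uniform(band.low, hi, spec.sinusoids_per_band)
        band_rms = profile.amplitude * np.sqrt(weight / total_w)
        amp = band_rms * np.sqrt(2.0 / spec.sinusoids_per_band)
        for f in freqs:
            phases = rng.uniform(0, 2 * np.pi, n_ch)
            signal += amp * np.sin(2 * np.pi * f * t[None, :]
                                   + phases[:, None])
    if profile.noise_floor > 0:
        signal += profile.noise_floor * rng.standard_normal((n_ch, samples))
    return signal


def simulate_subject(spec: SimSpec,
                     subject: int = 0) -> tuple[RawRecording, LabelSequence]:
    """A full synthetic recording with its hypnogram."""
    hypnogram = sample_hypnogram(spec, subject)
    rng = _subject_rng(spec, subject, 1)
    epochs = [synth_epoch(stage, spec, rng) for stage in hypnogram.labels]
    signal = np.concatenate(epochs, axis=1)
    rec = RawRecording(subject_id=f"synthetic-{subject:02d}",
                       sampling_rate=spec.rate,
                       channel_names=list(spec.channels),
                       signal=signal)
    return rec, hypnogram


def write_dataset(spec: SimSpec, out_dir: str | Path) -> list[tuple[Path, Path]]:
    """Write one EDF plus one hypnogram TSV per subject."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in range(spec.n_subjects):
        rec, hyp = simulate_subject(spec, s)
        edf = write_recording(out_dir / f"{rec.subject_id}.edf", rec)
        tsv = write_hypnogram_tsv(out_dir / f"{rec.subject_id}.tsv", hyp)
        paths.append((edf, tsv))
    return paths


def simulate_feature_dataset(spec: SimSpec, k: int = 4, d: int = 1,
                             bands: tuple[Band, ...] = DEFAULT_BANDS,
                             zscore: bool = True,
                             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate, extract DE features, and assemble context blocks in memory.

    Returns network-ready inputs ``x`` of shape (samples, bands,
    context_len, electrodes), integer stage labels ``y``, and the
    per-sample subject index.
    """
    xs, ys, subjects = [], [], []
    for s in range(spec.n_subjects):
        rec, hyp = simulate_subject(spec, s)
        epoched = epoch_signal(rec, spec.epoch_seconds, labels=hyp)
        feats = extract_features(epoched, bands)
        if zscore:
            feats = zscore_features(feats)
        ctx = assemble_contexts(feats, epoched.labels, k=k, d=d)
        xs.append(contexts_to_input(ctx.values))
        ys.append(ctx.labels)
        subjects.append(np.full(ctx.n_contexts, s))
    return (np.concatenate(xs), np.concatenate(ys), np.concatenate(subjects))
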