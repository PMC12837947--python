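"""Waveform loading and Log-Mel feature extraction.

The recognition pipeline operates on mono clips at 8 kHz, normalised to a
fixed duration of 1 s (``N = f0 * T = 8000`` samples).  Each clip is framed
with a 256-sample window and a 128-sample hop, the power spectrum is
projected through a 64-band mel filterbank, and the (natural) logarithm of
the floored band energies yields a 64 x 62 Log-Mel matrix.

The framing convention keeps the final partial frame by zero-padding the
signal tail, so an 8000-sample clip yields ``1 + ceil((8000-256)/128) = 62``
frames.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
from scipy.io import wavfile
from scipy.signal import get_window, resample_poly

DEFAULT_RATE = 8000
CLASS_NAMES = ("cough", "noise")  # one-hot column order; column 0 = cough


class ValidationError(ValueError):
    """Raised when an input violates a pipeline contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class AudioSegment:
    """A labelled mono waveform clip.

    ``samples`` are floats in [-1, 1]; ``label`` is one of ``"cough"``,
    ``"noise"`` or ``"unknown"``.
    """

    samples: np.ndarray
    rate: int = DEFAULT_RATE
    label: str = "unknown"
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate <= 0:
            raise ValidationError(f"rate must be positive, got {self.rate}")
        if self.samples.ndim != 1:
            raise ValidationError("AudioSegment samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("AudioSegment samples must be finite")

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class StftConfig:
    n_fft: int = 256
    hop_length: int = 128
    window: str = "hann"
    pad_mode: str = "tail"

    def __post_init__(self) -> None:
        if not (0 < self.hop_length <= self.n_fft):
            raise ValidationError(
                f"require 0 < hop_length <= n_fft, got hop={self.hop_length}, "
                f"n_fft={self.n_fft}"
            )


@dataclass
class MelFilterBank:
    weights: np.ndarray  # (n_mels, n_fft // 2 + 1), non-negative
    n_mels: int
    fmin: float
    fmax: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if np.any(self.weights < 0):
            raise ValidationError("mel filter weights must be non-negative")
        if not np.all(self.weights.max(axis=1) > 0):
            raise ValidationError("every mel filter row needs a positive entry")


@dataclass
class LogMelSpectrogram:
    values: np.ndarray  # (n_mels, frame_count)
    frame_count: int
    floor_eps: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != self.frame_count:
            raise ValidationError("LogMelSpectrogram shape/frame_count mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("LogMelSpectrogram entries must be finite")


@dataclass
class FeatureBatch:
    tensor: np.ndarray  # (B, n_mels, Tframe)
    labels: np.ndarray  # (B, 2) one-hot, column 0 = cough
    source_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.tensor.ndim != 3 or self.tensor.shape[0] < 1:
            raise ValidationError("feature tensor must be (B, n_mels, T), B >= 1")
        if self.labels.shape != (self.tensor.shape[0], 2):
            raise ValidationError("labels must be (B, 2) one-hot")
        if not np.all(self.labels.sum(axis=1) == 1):
            raise ValidationError("one-hot label rows must sum to 1")


# ---------------------------------------------------------------------------
# Loading and duration normalisation
# ---------------------------------------------------------------------------

_PCM_SCALE = {np.dtype(np.int16): 32768.0, np.dtype(np.int32): 2147483648.0}


def load_wav(path: str | Path, target_rate: int = DEFAULT_RATE,
             label: str = "unknown") -> AudioSegment:
    """Read a PCM/float RIFF WAV as a mono segment at ``target_rate``.

    Multi-channel audio is averaged to mono; integer PCM is rescaled to
    [-1, 1]; any remaining overshoot (e.g. float files) is peak-normalised.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with the offending path
        raise IOError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise ValidationError(f"zero-length audio in {path}")
    x = np.asarray(data)
    if x.dtype in _PCM_SCALE:
        x = x.astype(np.float64) / _PCM_SCALE[x.dtype]
    elif x.dtype == np.uint8:
        x = (x.astype(np.float64) - 128.0) / 128.0
    else:
        x = x.astype(np.float64)
    if x.ndim == 2:
        x = x.mean(axis=1)
    if rate != target_rate:
        g = math.gcd(int(target_rate), int(rate))
        x = resample_poly(x, target_rate // g, rate // g)
    peak = np.max(np.abs(x)) if x.size else 0.0
    if peak > 1.0:
        x = x / peak
    return AudioSegment(x, rate=target_rate, label=label, source_id=path.stem)


def normalize_duration(seg: AudioSegment, target_len: int = DEFAULT_RATE,
                       mode: str = "center-pad",
                       rng: np.random.Generator | None = None) -> AudioSegment:
    """Force a segment to exactly ``target_len`` samples.

    Shorter clips are zero-padded symmetrically; longer clips are cropped
    (``center-crop`` takes the middle window, ``random-crop`` a seeded random
    window).  ``mode`` only matters for over-length inputs.
    """
    if target_len <= 0:
        raise ValidationError("target_len must be positive")
    n = len(seg)
    if n == 0:
        raise ValidationError("cannot normalise an empty segment")
    if n == target_len:
        return seg
    if n < target_len:
        lead = (target_len - n) // 2
        out = np.zeros(target_len)
        out[lead:lead + n] = seg.samples
    else:
        if mode == "center-crop" or mode == "center-pad":
            start = (n - target_len) // 2
        elif mode == "random-crop":
            rng = rng if rng is not None else np.random.default_rng(0)
            start = int(rng.integers(0, n - target_len + 1))
        else:
            raise ValidationError(f"unknown crop mode {mode!r}")
        out = seg.samples[start:start + target_len]
    return AudioSegment(out, rate=seg.rate, label=seg.label,
                        source_id=seg.source_id)


# ---------------------------------------------------------------------------
# STFT framing and mel projection
# ---------------------------------------------------------------------------

def frame_count(n: int, cfg: StftConfig) -> int:
    """Number of STFT frames for an ``n``-sample signal.

    Tail-padding convention: the last partial frame is kept, so the count is
    ``1 + ceil((n - n_fft) / hop_length)``.
    """
    if n < cfg.n_fft:
        raise ValidationError(f"signal of {n} samples shorter than n_fft={cfg.n_fft}")
    return 1 + math.ceil((n - cfg.n_fft) / cfg.hop_length)


def hz_to_mel(f):
    """HTK mel scale."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def make_mel_filterbank(n_mels: int = 64, n_fft: int = 256,
                        rate: int = DEFAULT_RATE, fmin: float = 0.0,
                        fmax: float | None = None) -> MelFilterBank:
    """Triangular HTK-mel filterbank over the rFFT bins."""
    if fmax is None:
        fmax = rate / 2
    if not (0 <= fmin < fmax <= rate / 2):
        raise ValidationError("require 0 <= fmin < fmax <= Nyquist")
    n_bins = n_fft // 2 + 1
    bin_freqs = np.arange(n_bins) * rate / n_fft
    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    weights = np.zeros((n_mels, n_bins))
    for i in range(n_mels):
        lo, mid, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (bin_freqs - lo) / max(mid - lo, 1e-12)
        down = (hi - bin_freqs) / max(hi - mid, 1e-12)
        weights[i] = np.maximum(0.0, np.minimum(up, down))
    return MelFilterBank(weights, n_mels=n_mels, fmin=fmin, fmax=fmax)


def stft_power(samples: np.ndarray, cfg: StftConfig) -> np.ndarray:
    """Windowed power spectrogram, shape (n_fft//2 + 1, Tframe)."""
    n = samples.size
    t = frame_count(n, cfg)
    padded_len = (t - 1) * cfg.hop_length + cfg.n_fft
    x = np.zeros(padded_len)
    x[:n] = samples
    idx = (np.arange(cfg.n_fft)[None, :]
           + cfg.hop_length * np.arange(t)[:, None])
    frames = x[idx] * get_window(cfg.window, cfg.n_fft, fftbins=True)
    spec = np.fft.rfft(frames, axis=1)
    return (np.abs(spec) ** 2).T


def compute_log_mel(seg: AudioSegment, cfg: StftConfig | None = None,
                    bank: MelFilterBank | None = None,
                    floor_eps: float = 1e-10,
                    log_base: str = "natural") -> LogMelSpectrogram:
    """Log of floored mel-band energies; (64, 62) under defaults.

    ``log_base`` may be ``"natural"`` (default) or ``"10"``.
    """
    cfg = cfg if cfg is not None else StftConfig()
    bank = bank if bank is not None else make_mel_filterbank(
        n_fft=cfg.n_fft, rate=seg.rate)
    if floor_eps <= 0:
        raise ValidationError("floor_eps must be positive")
    power = stft_power(seg.samples, cfg)
    if bank.weights.shape[1] != power.shape[0]:
        raise ValidationError(
            f"filterbank expects {bank.weights.shape[1]} bins, STFT produced "
            f"{power.shape[0]}")
    energy = bank.weights @ power
    floored = np.maximum(energy, floor_eps)
    if log_base == "natural":
        values = np.log(floored)
    elif log_base == "10":
        values = np.log10(floored)
    else:
        raise ValidationError(f"unknown log_base {log_base!r}")
    return LogMelSpectrogram(values, frame_count=power.shape[1],
                             floor_eps=floor_eps)


# ---------------------------------------------------------------------------
# Batching and archives
# ---------------------------------------------------------------------------

def labels_to_onehot(labels: Sequence[str]) -> np.ndarray:
    out = np.zeros((len(labels), 2), dtype=np.int8)
    for i, lab in enumerate(labels):
        if lab not in CLASS_NAMES:
            raise ValidationError(f"unknown label {lab!r}")
        out[i, CLASS_NAMES.index(lab)] = 1
    return out


def batch_features(specs: Iterable[LogMelSpectrogram],
                   labels: Sequence[str],
                   source_ids: Sequence[str] | None = None) -> FeatureBatch:
    """Stack spectrograms into a (B, n_mels, Tframe) tensor with one-hot labels."""
    specs = list(specs)
    if not specs:
        raise ValidationError("empty batch")
    shapes = {s.values.shape for s in specs}
    if len(shapes) != 1:
        raise ValidationError(f"heterogeneous spectrogram shapes: {sorted(shapes)}")
    tensor = np.stack([s.values for s in specs])
    onehot = labels_to_onehot(labels)
    if onehot.shape[0] != tensor.shape[0]:
        raise ValidationError("label count does not match batch size")
    ids = list(source_ids) if source_ids is not None else [""] * len(specs)
    return FeatureBatch(tensor, onehot, ids)


def save_feature_archive(path: str | Path, batch: FeatureBatch,
                         cfg: StftConfig, bank: MelFilterBank) -> None:
    """HDF5 archive (features/labels/source ids) plus a JSON provenance sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=batch.tensor.astype(np.float32))
        f.create_dataset("labels", data=batch.labels.astype(np.int8))
        f.create_dataset("source_ids",
                         data=np.array(batch.source_ids, dtype=object),
                         dtype=h5py.string_dtype())
    sidecar = {
        "stft": asdict(cfg),
        "mel": {"n_mels": bank.n_mels, "fmin": bank.fmin, "fmax": bank.fmax},
        "class_order": list(CLASS_NAMES),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2))


def load_feature_archive(path: str | Path) -> FeatureBatch:
    with h5py.File(path, "r") as f:
        tensor = f["features"][()].astype(np.float64)
        labels = f["labels"][()].astype(np.int8)
        ids = [s.decode() if isinstance(s, bytes) else str(s)
               for s in f["source_ids"][()]]
    return FeatureBatch(tensor, labels, ids)
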