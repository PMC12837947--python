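"""Frozen CNN14-style convolutional backbone.

Maps a Log-Mel batch (B, 1, 64, 62) to a 2048-d clip embedding.  The
topology is the canonical CNN14 convolutional trunk: an input batch-norm
over the mel axis, then six VGG-style blocks of two 3x3 conv + BN + ReLU
layers with channel widths 64-128-256-512-1024-2048, 2x2 average pooling
after the first five blocks, and global average pooling at the end.  The
backbone is always frozen: batch-norm runs in inference mode and no tensor
ever receives an update.

Weights come either from a reproducible random initialisation (the default
fixture; He-scaled convs, identity batch-norms) or from an HDF5 archive of
pretrained tensors laid out per :data:`PRETRAINED_NAME_MAP`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .audio import FeatureBatch, ValidationError

BN_EPS = 1e-5


@dataclass
class BackboneConfig:
    block_channel_widths: tuple[int, ...] = (64, 128, 256, 512, 1024, 2048)
    convs_per_block: int = 2
    kernel: int = 3
    n_mels: int = 64
    embedding_dim: int = 2048

    def __post_init__(self) -> None:
        widths = self.block_channel_widths
        if any(b >= a for a, b in zip(widths[1:], widths)):
            raise ValidationError("block widths must be strictly increasing")
        if self.embedding_dim != widths[-1]:
            raise ValidationError("embedding_dim must equal the last block width")


@dataclass
class BackboneWeights:
    """Per-layer tensors keyed ``block{i}/conv{j}`` and ``block{i}/bn{j}``
    (plus ``input_bn``); always frozen."""
    tensors: dict[str, np.ndarray] = field(default_factory=dict)
    frozen: bool = True

    def state_hash(self) -> bytes:
        """Concatenated raw bytes of every tensor, for bit-identity checks."""
        import hashlib
        h = hashlib.sha256()
        for name in sorted(self.tensors):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.tensors[name]).tobytes())
        return h.digest()


def _expected_tensor_names(cfg: BackboneConfig) -> list[str]:
    names = ["input_bn/mean", "input_bn/var", "input_bn/gamma", "input_bn/beta"]
    for i in range(len(cfg.block_channel_widths)):
        for j in range(cfg.convs_per_block):
            names.append(f"block{i}/conv{j}/weight")
            for p in ("gamma", "beta", "mean", "var"):
                names.append(f"block{i}/bn{j}/{p}")
    return names


def init_random(cfg: BackboneConfig | None = None, seed: int = 0,
                input_stats: tuple[float, float] | None = None) -> BackboneWeights:
    """Reproducible He-initialised frozen backbone.

    ``input_stats`` supplies (mean, var) for the input batch-norm; log-mel
    features sit far from zero mean / unit variance, so fitting these once on
    the training features keeps the random conv stack in its linear range.
    """
    cfg = cfg if cfg is not None else BackboneConfig()
    rng = np.random.default_rng(seed)
    tensors: dict[str, np.ndarray] = {}
    mean, var = input_stats if input_stats is not None else (0.0, 1.0)
    tensors["input_bn/mean"] = np.full(cfg.n_mels, mean, dtype=np.float32)
    tensors["input_bn/var"] = np.full(cfg.n_mels, var, dtype=np.float32)
    tensors["input_bn/gamma"] = np.ones(cfg.n_mels, dtype=np.float32)
    tensors["input_bn/beta"] = np.zeros(cfg.n_mels, dtype=np.float32)
    in_ch = 1
    k = cfg.kernel
    for i, width in enumerate(cfg.block_channel_widths):
        for j in range(cfg.convs_per_block):
            fan_in = in_ch * k * k
            w = rng.standard_normal((width, in_ch, k, k)) * np.sqrt(2.0 / fan_in)
            tensors[f"block{i}/conv{j}/weight"] = w.astype(np.float32)
            tensors[f"block{i}/bn{j}/gamma"] = np.ones(width, dtype=np.float32)
            tensors[f"block{i}/bn{j}/beta"] = np.zeros(width, dtype=np.float32)
            tensors[f"block{i}/bn{j}/mean"] = np.zeros(width, dtype=np.float32)
            tensors[f"block{i}/bn{j}/var"] = np.ones(width, dtype=np.float32)
            in_ch = width
    return BackboneWeights(tensors, frozen=True)


# Mapping from the published AudioSet-pretrained CNN14 parameter names to the
# archive layout this module reads.  A conversion script (run wherever torch
# is available) only has to copy tensors under these HDF5 paths.
PRETRAINED_NAME_MAP: dict[str, str] = {"bn0.running_mean": "input_bn/mean",
                                       "bn0.running_var": "input_bn/var",
                                       "bn0.weight": "input_bn/gamma",
                                       "bn0.bias": "input_bn/beta"}
for _i in range(6):
    for _j in (1, 2):
        _src = f"conv_block{_i + 1}.conv{_j}.weight"
        PRETRAINED_NAME_MAP[_src] = f"block{_i}/conv{_j - 1}/weight"
        _bn = f"conv_block{_i + 1}.bn{_j}"
        PRETRAINED_NAME_MAP[f"{_bn}.weight"] = f"block{_i}/bn{_j - 1}/gamma"
        PRETRAINED_NAME_MAP[f"{_bn}.bias"] = f"block{_i}/bn{_j - 1}/beta"
        PRETRAINED_NAME_MAP[f"{_bn}.running_mean"] = f"block{_i}/bn{_j - 1}/mean"
        PRETRAINED_NAME_MAP[f"{_bn}.running_var"] = f"block{_i}/bn{_j - 1}/var"


class WeightLoadError(RuntimeError):
    pass


def load_pretrained(archive: str, cfg: BackboneConfig | None = None
                    ) -> BackboneWeights:
    """Load backbone tensors from an HDF5 weight archive.

    Raises :class:`WeightLoadError` listing every absent or mis-shaped
    tensor.  Extra datasets in the archive are ignored (the published
    checkpoint also carries embedding/classifier layers this trunk omits).
    """
    cfg = cfg if cfg is not None else BackboneConfig()
    expected = _expected_tensor_names(cfg)
    tensors: dict[str, np.ndarray] = {}
    problems: list[str] = []
    try:
        f = h5py.File(archive, "r")
    except Exception as exc:  # noqa: BLE001
        raise WeightLoadError(f"cannot open weight archive {archive}: {exc}")
    with f:
        for name in expected:
            if name not in f:
                problems.append(f"missing: {name}")
                continue
            arr = np.asarray(f[name][()], dtype=np.float32)
            tensors[name] = arr
    widths = cfg.block_channel_widths
    in_ch = 1
    for i, width in enumerate(widths):
        for j in range(cfg.convs_per_block):
            key = f"block{i}/conv{j}/weight"
            want = (width, in_ch, cfg.kernel, cfg.kernel)
            if key in tensors and tensors[key].shape != want:
                problems.append(f"shape mismatch: {key} has "
                                f"{tensors[key].shape}, expected {want}")
            in_ch = width
    if problems:
        raise WeightLoadError("weight archive incompatible:\n  "
                              + "\n  ".join(problems))
    return BackboneWeights(tensors, frozen=True)


def save_weights(archive: str, weights: BackboneWeights) -> None:
    with h5py.File(archive, "w") as f:
        for name, arr in weights.tensors.items():
            f.create_dataset(name, data=arr)


# ---------------------------------------------------------------------------
# Forward pass
# ---------------------------------------------------------------------------

def expand_input(batch: FeatureBatch | np.ndarray) -> np.ndarray:
    """Insert the channel axis: (B, 64, 62) -> (B, 1, 64, 62)."""
    x = batch.tensor if isinstance(batch, FeatureBatch) else np.asarray(batch)
    if x.ndim != 3:
        raise ValidationError(f"expected rank-3 feature tensor, got rank {x.ndim}")
    return x[:, None, :, :]


def conv2d_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """3x3 same-padding convolution via im2col + GEMM. x: (B,C,H,W), w: (O,C,3,3)."""
    b, c, h, wd = x.shape
    o = w.shape[0]
    k = w.shape[2]
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * wd, c * k * k)
    out = cols @ w.reshape(o, c * k * k).T
    return out.reshape(b, h, wd, o).transpose(0, 3, 1, 2)


def _bn_eval(x: np.ndarray, mean, var, gamma, beta, channel_axis: int = 1
             ) -> np.ndarray:
    shape = [1] * x.ndim
    shape[channel_axis] = -1
    return ((x - mean.reshape(shape)) / np.sqrt(var.reshape(shape) + BN_EPS)
            * gamma.reshape(shape) + beta.reshape(shape))


def _avg_pool2(x: np.ndarray) -> np.ndarray:
    h2, w2 = x.shape[2] // 2, x.shape[3] // 2
    x = x[:, :, :h2 * 2, :w2 * 2]
    return x.reshape(x.shape[0], x.shape[1], h2, 2, w2, 2).mean(axis=(3, 5))


def global_average_pool(h: np.ndarray) -> np.ndarray:
    """(B, C, H, W) -> (B, C) by averaging the spatiotemporal axes."""
    return h.mean(axis=(2, 3))


def embed(x: np.ndarray, weights: BackboneWeights,
          cfg: BackboneConfig | None = None) -> np.ndarray:
    """Frozen forward pass: (B, 1, 64, 62) -> (B, 2048) embeddings.

    Deterministic for fixed weights and input; batch-norm always uses the
    stored (inference-mode) statistics.
    """
    cfg = cfg if cfg is not None else BackboneConfig()
    x = np.asarray(x, dtype=np.float32)
    if x.ndim != 4 or x.shape[1] != 1:
        raise ValidationError(f"expected (B, 1, n_mels, T), got {x.shape}")
    t = weights.tensors
    missing = [n for n in _expected_tensor_names(cfg) if n not in t]
    if missing:
        raise WeightLoadError("weights incompatible with config; missing:\n  "
                              + "\n  ".join(missing))
    # input normalisation over the mel axis (axis 2 with a single channel)
    x = _bn_eval(x, t["input_bn/mean"], t["input_bn/var"],
                 t["input_bn/gamma"], t["input_bn/beta"], channel_axis=2)
    n_blocks = len(cfg.block_channel_widths)
    for i in range(n_blocks):
        for j in range(cfg.convs_per_block):
            x = conv2d_same(x, t[f"block{i}/conv{j}/weight"])
            x = _bn_eval(x, t[f"block{i}/bn{j}/mean"], t[f"block{i}/bn{j}/var"],
                         t[f"block{i}/bn{j}/gamma"], t[f"block{i}/bn{j}/beta"])
            np.maximum(x, 0.0, out=x)
        if i < n_blocks - 1:
            x = _avg_pool2(x)
    if min(x.shape[2], x.shape[3]) < 1:
        raise ValidationError("input too small to survive the pooling cascade")
    return global_average_pool(x).astype(np.float64)


def embed_corpus(features: np.ndarray, weights: BackboneWeights,
                 cfg: BackboneConfig | None = None, chunk: int = 8
                 ) -> np.ndarray:
    """Embed (N, 64, 62) features in chunks; returns (N, 2048)."""
    out = []
    for i in range(0, features.shape[0], chunk):
        out.append(embed(expand_input(features[i:i + chunk]), weights, cfg))
    return np.concatenate(out, axis=0)
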