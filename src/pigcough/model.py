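"""Fusion classifier: backbone embedding + TFDS descriptor -> cough probability.

The default head concatenates the 2048-d frozen-backbone embedding with the
128-d TFDS descriptor (2176-d fused feature), applies inverted dropout
(p = 0.2), a single fully connected layer to two logits, and a numerically
stable two-class softmax.  Column 0 of every probability array is the cough
class.

Ablation variants are configuration switches:
  * no TFDS       -- backbone embedding only (head sees 2048 dims);
  * no backbone   -- TFDS descriptor only (head sees 128 dims);
  * add fusion    -- backbone embedding linearly projected to 128 dims and
                     summed with the TFDS descriptor;
  * no stratified learning rate -- a trainer-level switch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np

from .audio import ValidationError
from .backbone import BackboneConfig, BackboneWeights
from .tfds import TfdsConfig, TfdsParams, init_tfds_params, tfds_forward, \
    tfds_backward


@dataclass
class VariantConfig:
    use_tfds: bool = True
    use_backbone: bool = True
    fusion: str = "concat"          # "concat" or "add"
    stratified_lr: bool = True

    def __post_init__(self) -> None:
        if not (self.use_tfds or self.use_backbone):
            raise ValidationError("at least one stream must be enabled")
        if self.fusion not in ("concat", "add"):
            raise ValidationError(f"unknown fusion mode {self.fusion!r}")
        if self.fusion == "add" and not (self.use_tfds and self.use_backbone):
            raise ValidationError("add fusion requires both streams")


@dataclass
class ClassifierParams:
    w: np.ndarray   # (2, fused_dim); z = W h + b
    b: np.ndarray   # (2,)

    def n_trainable(self) -> int:
        return self.w.size + self.b.size


def fused_dim(variant: VariantConfig, embedding_dim: int = 2048,
              hidden_dim: int = 128) -> int:
    if variant.fusion == "add":
        return hidden_dim
    d = 0
    if variant.use_backbone:
        d += embedding_dim
    if variant.use_tfds:
        d += hidden_dim
    return d


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def fuse(g14: np.ndarray | None, g_tfds: np.ndarray | None,
         mode: str = "concat", proj_w: np.ndarray | None = None,
         proj_b: np.ndarray | None = None) -> np.ndarray:
    """Fuse the two stream outputs (batched, (B, d) each).

    ``concat`` places the backbone embedding first; ``add`` projects it to
    the TFDS width and sums.  A disabled stream is passed as ``None``.
    """
    if mode == "concat":
        parts = [v for v in (g14, g_tfds) if v is not None]
        if not parts:
            raise ValidationError("no stream to fuse")
        return np.concatenate(parts, axis=1)
    if g14 is None or g_tfds is None:
        raise ValidationError("add fusion requires both streams")
    if proj_w is None:
        raise ValidationError("add fusion requires a projection")
    proj = g14 @ proj_w.T + (proj_b if proj_b is not None else 0.0)
    return proj + g_tfds


def make_dropout_mask(shape: tuple[int, ...], p: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Bernoulli keep-mask with keep probability 1 - p."""
    return (rng.random(shape) >= p).astype(np.float64)


def apply_dropout(v: np.ndarray, mask: np.ndarray | None, p: float,
                  training: bool) -> np.ndarray:
    """Inverted dropout: training -> (1/(1-p)) * (m * v); inference -> v."""
    if not training or p == 0.0:
        return v
    if mask is None or mask.shape != v.shape:
        raise ValidationError("dropout mask shape mismatch")
    return mask * v / (1.0 - p)


def logits(h: np.ndarray, params: ClassifierParams) -> np.ndarray:
    """Affine map to two logits: z = W h + b (batched: (B, D) -> (B, 2))."""
    if h.shape[-1] != params.w.shape[1]:
        raise ValidationError(
            f"head expects {params.w.shape[1]}-d input, got {h.shape[-1]}")
    return h @ params.w.T + params.b


def softmax2(z: np.ndarray) -> np.ndarray:
    """Stable two-class softmax; rows sum to 1. Accepts (2,) or (B, 2)."""
    z = np.asarray(z, dtype=np.float64)
    single = z.ndim == 1
    if single:
        z = z[None, :]
    shifted = z - z.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    p = e / e.sum(axis=1, keepdims=True)
    return p[0] if single else p


# ---------------------------------------------------------------------------
# Assembled model
# ---------------------------------------------------------------------------

@dataclass
class CoughModel:
    """The trainable part of the recogniser plus a handle on the frozen backbone.

    The backbone itself is applied separately (its output embedding ``g14``
    is a precomputable, constant function of the input because it is frozen);
    ``forward`` consumes the Log-Mel batch together with the matching
    embeddings.
    """
    variant: VariantConfig = field(default_factory=VariantConfig)
    tfds_cfg: TfdsConfig = field(default_factory=TfdsConfig)
    backbone_cfg: BackboneConfig = field(default_factory=BackboneConfig)
    tfds: TfdsParams | None = None
    head: ClassifierParams | None = None
    proj_w: np.ndarray | None = None   # add-fusion projection (hidden, 2048)
    proj_b: np.ndarray | None = None
    dropout_p: float = 0.2
    backbone_weights: BackboneWeights | None = None

    @classmethod
    def build(cls, variant: VariantConfig | None = None,
              tfds_cfg: TfdsConfig | None = None,
              backbone_cfg: BackboneConfig | None = None,
              backbone_weights: BackboneWeights | None = None,
              dropout_p: float = 0.2, seed: int = 0) -> "CoughModel":
        variant = variant if variant is not None else VariantConfig()
        tfds_cfg = tfds_cfg if tfds_cfg is not None else TfdsConfig()
        backbone_cfg = backbone_cfg if backbone_cfg is not None else BackboneConfig()
        rng = np.random.default_rng(seed)
        m = cls(variant=variant, tfds_cfg=tfds_cfg, backbone_cfg=backbone_cfg,
                dropout_p=dropout_p, backbone_weights=backbone_weights)
        if variant.use_tfds:
            m.tfds = init_tfds_params(tfds_cfg,
                                      seed=int(rng.integers(2 ** 31)))
        d = fused_dim(variant, backbone_cfg.embedding_dim, tfds_cfg.hidden_dim)
        m.head = ClassifierParams(
            w=rng.standard_normal((2, d)) * np.sqrt(1.0 / d),
            b=np.zeros(2))
        if variant.fusion == "add":
            e = backbone_cfg.embedding_dim
            m.proj_w = rng.standard_normal((tfds_cfg.hidden_dim, e)) \
                * np.sqrt(1.0 / e)
            m.proj_b = np.zeros(tfds_cfg.hidden_dim)
        return m

    # -- forward -----------------------------------------------------------

    def forward(self, features: np.ndarray, g14: np.ndarray | None,
                training: bool = False,
                rng: np.random.Generator | None = None,
                cache: dict | None = None) -> np.ndarray:
        """Probabilities (B, 2) from Log-Mel features and backbone embeddings."""
        features = np.asarray(features, dtype=np.float64)
        b = features.shape[0]
        g_tfds = None
        tfds_cache: dict = {}
        if self.variant.use_tfds:
            g_tfds = tfds_forward(features, self.tfds_cfg, self.tfds,
                                  training=training, cache=tfds_cache)
        g_bb = None
        if self.variant.use_backbone:
            if g14 is None:
                raise ValidationError("backbone stream enabled but g14 missing")
            g_bb = np.asarray(g14, dtype=np.float64)
        fusedv = fuse(g_bb, g_tfds, self.variant.fusion,
                      self.proj_w, self.proj_b)
        mask = None
        if training:
            rng = rng if rng is not None else np.random.default_rng(0)
            mask = make_dropout_mask(fusedv.shape, self.dropout_p, rng)
        h = apply_dropout(fusedv, mask, self.dropout_p, training)
        z = logits(h, self.head)
        p = softmax2(z)
        if cache is not None:
            cache.update(tfds=tfds_cache, g_tfds=g_tfds, g14=g_bb,
                         fused=fusedv, mask=mask, h=h, z=z, p=p,
                         training=training)
        return p

    # -- backward ----------------------------------------------------------

    def backward(self, labels_onehot: np.ndarray, cache: dict
                 ) -> dict[str, dict[str, np.ndarray]]:
        """Gradients of the mean cross-entropy w.r.t. every trainable group.

        Gradient flow into the frozen backbone is discarded by construction:
        the chain from dL/d(fused) into g14 is never evaluated.
        Returns ``{"head": {...}, "tfds": {...}, "proj": {...}}`` (groups
        present only when their parameters exist).
        """
        p, h = cache["p"], cache["h"]
        k = p.shape[0]
        dz = (p - labels_onehot) / k                      # (B, 2)
        grads: dict[str, dict[str, np.ndarray]] = {
            "head": {"w": dz.T @ h, "b": dz.sum(axis=0)}}
        dh = dz @ self.head.w                            # (B, D)
        if cache["training"] and self.dropout_p > 0:
            dfused = dh * cache["mask"] / (1.0 - self.dropout_p)
        else:
            dfused = dh
        if self.variant.fusion == "add":
            g14 = cache["g14"]
            grads["proj"] = {"w": dfused.T @ g14, "b": dfused.sum(axis=0)}
            dg_tfds = dfused
        elif self.variant.use_tfds:
            off = self.backbone_cfg.embedding_dim if self.variant.use_backbone else 0
            dg_tfds = dfused[:, off:off + self.tfds_cfg.hidden_dim]
        else:
            dg_tfds = None
        if dg_tfds is not None:
            grads["tfds"] = tfds_backward(dg_tfds, self.tfds_cfg, self.tfds,
                                          cache["tfds"])
        return grads

    # -- parameter bookkeeping --------------------------------------------

    def trainable_groups(self) -> dict[str, dict[str, np.ndarray]]:
        groups: dict[str, dict[str, np.ndarray]] = {
            "head": {"w": self.head.w, "b": self.head.b}}
        if self.variant.use_tfds:
            groups["tfds"] = {n: getattr(self.tfds, n)
                              for n in TfdsParams.TRAINABLE}
        if self.variant.fusion == "add":
            groups["proj"] = {"w": self.proj_w, "b": self.proj_b}
        return groups

    def set_group(self, name: str, tensors: dict[str, np.ndarray]) -> None:
        if name == "head":
            self.head.w, self.head.b = tensors["w"], tensors["b"]
        elif name == "tfds":
            for k, v in tensors.items():
                setattr(self.tfds, k, v)
        elif name == "proj":
            self.proj_w, self.proj_b = tensors["w"], tensors["b"]
        else:
            raise ValidationError(f"unknown parameter group {name!r}")

    def count_trainable(self) -> int:
        """Scalars receiving gradient updates; the frozen backbone adds 0."""
        return sum(t.size for g in self.trainable_groups().values()
                   for t in g.values())


# ---------------------------------------------------------------------------
# Checkpoint serialisation
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, model: CoughModel) -> None:
    """Directory checkpoint: weights.h5 plus config.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with h5py.File(path / "weights.h5", "w") as f:
        for gname, tensors in model.trainable_groups().items():
            for tname, arr in tensors.items():
                f.create_dataset(f"{gname}/{tname}", data=arr)
        if model.variant.use_tfds:
            f.create_dataset("tfds_state/bn_mean", data=model.tfds.bn_mean)
            f.create_dataset("tfds_state/bn_var", data=model.tfds.bn_var)
        if model.backbone_weights is not None:
            for name, arr in model.backbone_weights.tensors.items():
                f.create_dataset(f"backbone/{name}", data=arr)
    cfg = {"variant": asdict(model.variant), "tfds": asdict(model.tfds_cfg),
           "backbone": asdict(model.backbone_cfg),
           "dropout_p": model.dropout_p}
    (path / "config.json").write_text(json.dumps(cfg, indent=2))


def load_checkpoint(path: str | Path) -> CoughModel:
    path = Path(path)
    cfg = json.loads((path / "config.json").read_text())
    backbone_cfg_d = cfg["backbone"]
    backbone_cfg_d["block_channel_widths"] = tuple(
        backbone_cfg_d["block_channel_widths"])
    model = CoughModel.build(
        variant=VariantConfig(**cfg["variant"]),
        tfds_cfg=TfdsConfig(**cfg["tfds"]),
        backbone_cfg=BackboneConfig(**backbone_cfg_d),
        dropout_p=cfg["dropout_p"])
    with h5py.File(path / "weights.h5", "r") as f:
        for gname in list(model.trainable_groups()):
            tensors = {t: f[f"{gname}/{t}"][()] for t in f[gname]}
            model.set_group(gname, tensors)
        if model.variant.use_tfds and "tfds_state" in f:
            model.tfds.bn_mean = f["tfds_state/bn_mean"][()]
            model.tfds.bn_var = f["tfds_state/bn_var"][()]
        if "backbone" in f:
            tensors = {}
            def _collect(name, obj):
                if isinstance(obj, h5py.Dataset):
                    tensors[name] = obj[()]
            f["backbone"].visititems(_collect)
            model.backbone_weights = BackboneWeights(tensors, frozen=True)
    return model
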