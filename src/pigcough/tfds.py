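"""Time-Frequency Dual-Stream (TFDS) covariance descriptor.

The trainable branch that complements the frozen backbone.  From a Log-Mel
batch X (B, 64, T) it computes:

1. a 1x1 convolution over the mel axis to ``subbands`` channels, batch-norm,
   ReLU  ->  Z (B, 32, 62);
2. the temporal Gram matrix C_t (frame-by-frame inner products, T x T) and
   the spectral Gram matrix C_f (band-by-band inner products, S x S) --
   raw second-order statistics, uncentred and unnormalised;
3. adaptive average pooling of each Gram matrix to fixed sizes
   (25 x 25 and 16 x 16), flattening, and concatenation into an 881-d vector;
4. a fully connected projection with ReLU to a 128-d descriptor g_tfds.

``tfds_backward`` implements the exact reverse-mode gradients of this chain
(including training-mode batch-norm), used by the trainer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .audio import ValidationError

BN_EPS = 1e-5


@dataclass
class TfdsConfig:
    subbands: int = 32
    t_max: int = 25
    s_max: int = 16
    hidden_dim: int = 128
    n_mels: int = 64

    def __post_init__(self) -> None:
        if min(self.subbands, self.t_max, self.s_max, self.hidden_dim) < 1:
            raise ValidationError("all TFDS sizes must be positive")

    @property
    def flat_dim(self) -> int:
        return self.t_max ** 2 + self.s_max ** 2


@dataclass
class TfdsParams:
    """Trainable tensors of the TFDS branch plus batch-norm running stats."""
    conv_w: np.ndarray      # (subbands, n_mels) 1x1 conv over mel bins
    conv_b: np.ndarray      # (subbands,)
    bn_gamma: np.ndarray    # (subbands,)
    bn_beta: np.ndarray     # (subbands,)
    bn_mean: np.ndarray     # running mean, not trainable
    bn_var: np.ndarray      # running var, not trainable
    w_proj: np.ndarray      # (hidden_dim, flat_dim)
    b_proj: np.ndarray      # (hidden_dim,)
    bn_momentum: float = 0.1

    TRAINABLE = ("conv_w", "conv_b", "bn_gamma", "bn_beta", "w_proj", "b_proj")

    def n_trainable(self) -> int:
        return sum(getattr(self, n).size for n in self.TRAINABLE)


def init_tfds_params(cfg: TfdsConfig | None = None, seed: int = 0) -> TfdsParams:
    cfg = cfg if cfg is not None else TfdsConfig()
    rng = np.random.default_rng(seed)
    s, m = cfg.subbands, cfg.n_mels
    return TfdsParams(
        conv_w=rng.standard_normal((s, m)) * np.sqrt(2.0 / m),
        conv_b=np.zeros(s),
        bn_gamma=np.ones(s),
        bn_beta=np.zeros(s),
        bn_mean=np.zeros(s),
        bn_var=np.ones(s),
        w_proj=rng.standard_normal((cfg.hidden_dim, cfg.flat_dim))
        * np.sqrt(2.0 / cfg.flat_dim),
        b_proj=np.zeros(cfg.hidden_dim),
    )


# ---------------------------------------------------------------------------
# Forward stages
# ---------------------------------------------------------------------------

def project_subbands(x: np.ndarray, params: TfdsParams, training: bool = False,
                     cache: dict | None = None) -> np.ndarray:
    """1x1 conv over mel bins + batch-norm + ReLU: (B, n_mels, T) -> (B, S, T).

    Training mode uses batch statistics (and updates the running estimates);
    inference uses the running statistics.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3 or x.shape[1] != params.conv_w.shape[1]:
        raise ValidationError(
            f"expected (B, {params.conv_w.shape[1]}, T) input, got {x.shape}")
    pre = np.matmul(params.conv_w, x) + params.conv_b[None, :, None]
    if training:
        mu = pre.mean(axis=(0, 2))
        var = pre.var(axis=(0, 2))
        params.bn_mean = (1 - params.bn_momentum) * params.bn_mean \
            + params.bn_momentum * mu
        params.bn_var = (1 - params.bn_momentum) * params.bn_var \
            + params.bn_momentum * var
    else:
        mu, var = params.bn_mean, params.bn_var
    inv_std = 1.0 / np.sqrt(var + BN_EPS)
    xhat = (pre - mu[None, :, None]) * inv_std[None, :, None]
    bn = params.bn_gamma[None, :, None] * xhat + params.bn_beta[None, :, None]
    z = np.maximum(bn, 0.0)
    if cache is not None:
        cache.update(x=x, xhat=xhat, inv_std=inv_std, bn=bn, training=training)
    return z


def temporal_covariance(z: np.ndarray) -> np.ndarray:
    """Frame Gram matrices: out[b, i, j] = sum_s Z[b, s, i] Z[b, s, j]."""
    z = np.asarray(z, dtype=np.float64)
    return np.matmul(z.transpose(0, 2, 1), z)


def spectral_covariance(z: np.ndarray) -> np.ndarray:
    """Band Gram matrices: out[b, a, c] = sum_t Z[b, a, t] Z[b, c, t]."""
    z = np.asarray(z, dtype=np.float64)
    return np.matmul(z, z.transpose(0, 2, 1))


def pooling_matrix(n: int, m: int) -> np.ndarray:
    """(m, n) averaging matrix for 1-D adaptive average pooling.

    Region ``i`` covers indices ``[floor(i*n/m), ceil((i+1)*n/m))`` with
    uniform weights, matching the usual deep-learning adaptive-pool contract.
    """
    if not (1 <= m <= n):
        raise ValidationError(f"require 1 <= m <= n, got m={m}, n={n}")
    p = np.zeros((m, n))
    for i in range(m):
        lo = (i * n) // m
        hi = -(-((i + 1) * n) // m)  # ceil
        p[i, lo:hi] = 1.0 / (hi - lo)
    return p


def adaptive_pool(c: np.ndarray, m: int) -> np.ndarray:
    """Adaptive 2-D average pooling of square matrices to (m, m).

    Accepts (n, n) or batched (B, n, n).
    """
    c = np.asarray(c, dtype=np.float64)
    n = c.shape[-1]
    if c.shape[-2] != n:
        raise ValidationError("adaptive_pool expects square matrices")
    p = pooling_matrix(n, m)
    if c.ndim == 2:
        return p @ c @ p.T
    return np.matmul(np.matmul(p, c), p.T)


def flatten_concat(ct_pooled: np.ndarray, cf_pooled: np.ndarray,
                   cfg: TfdsConfig) -> np.ndarray:
    """Row-major flatten of pooled C_t then pooled C_f: (B, t_max^2 + s_max^2)."""
    if ct_pooled.shape[-2:] != (cfg.t_max, cfg.t_max) \
            or cf_pooled.shape[-2:] != (cfg.s_max, cfg.s_max):
        raise ValidationError("pooled matrices do not match the TFDS config")
    b = ct_pooled.shape[0]
    return np.concatenate([ct_pooled.reshape(b, -1), cf_pooled.reshape(b, -1)],
                          axis=1)


def tfds_forward(x: np.ndarray, cfg: TfdsConfig, params: TfdsParams,
                 training: bool = False, cache: dict | None = None
                 ) -> np.ndarray:
    """Full chain: Log-Mel batch (B, 64, T) -> descriptor g_tfds (B, 128)."""
    sub_cache: dict = {}
    z = project_subbands(x, params, training=training, cache=sub_cache)
    ct = temporal_covariance(z)
    cf = spectral_covariance(z)
    ct_p = adaptive_pool(ct, cfg.t_max)
    cf_p = adaptive_pool(cf, cfg.s_max)
    flat = flatten_concat(ct_p, cf_p, cfg)
    pre = flat @ params.w_proj.T + params.b_proj
    g = np.maximum(pre, 0.0)
    if cache is not None:
        cache.update(sub=sub_cache, z=z, flat=flat, pre=pre,
                     pt=pooling_matrix(ct.shape[-1], cfg.t_max),
                     ps=pooling_matrix(cf.shape[-1], cfg.s_max))
    return g


# ---------------------------------------------------------------------------
# Backward
# ---------------------------------------------------------------------------

def tfds_backward(dg: np.ndarray, cfg: TfdsConfig, params: TfdsParams,
                  cache: dict) -> dict[str, np.ndarray]:
    """Reverse-mode gradients of ``tfds_forward`` w.r.t. every trainable tensor.

    ``dg`` is dL/dg_tfds, shape (B, hidden_dim).  Returns a dict keyed like
    :attr:`TfdsParams.TRAINABLE` (the input gradient is not propagated
    further: upstream of this branch sits only the fixed Log-Mel extractor).
    """
    z, flat, pre = cache["z"], cache["flat"], cache["pre"]
    pt, ps = cache["pt"], cache["ps"]
    b = z.shape[0]
    dpre = dg * (pre > 0)
    grads: dict[str, np.ndarray] = {
        "w_proj": dpre.T @ flat,
        "b_proj": dpre.sum(axis=0),
    }
    dflat = dpre @ params.w_proj
    t2 = cfg.t_max ** 2
    dct_p = dflat[:, :t2].reshape(b, cfg.t_max, cfg.t_max)
    dcf_p = dflat[:, t2:].reshape(b, cfg.s_max, cfg.s_max)
    dct = np.matmul(np.matmul(pt.T, dct_p), pt)  # P^T dC' P
    dcf = np.matmul(np.matmul(ps.T, dcf_p), ps)
    # C_t[b] = Z_b^T Z_b  =>  dZ_b += Z_b (dC_t + dC_t^T)
    dz = np.matmul(z, dct + dct.transpose(0, 2, 1))
    # C_f[b] = Z_b Z_b^T  =>  dZ_b += (dC_f + dC_f^T) Z_b
    dz += np.matmul(dcf + dcf.transpose(0, 2, 1), z)
    # ReLU
    dbn = dz * (cache["sub"]["bn"] > 0)
    xhat, inv_std = cache["sub"]["xhat"], cache["sub"]["inv_std"]
    grads["bn_gamma"] = (dbn * xhat).sum(axis=(0, 2))
    grads["bn_beta"] = dbn.sum(axis=(0, 2))
    if cache["sub"]["training"]:
        n = b * z.shape[2]
        gamma = params.bn_gamma[None, :, None]
        istd = inv_std[None, :, None]
        mean_d = dbn.mean(axis=(0, 2), keepdims=True)
        mean_dx = (dbn * xhat).mean(axis=(0, 2), keepdims=True)
        dpre_conv = gamma * istd * (dbn - mean_d - xhat * mean_dx)
    else:
        dpre_conv = params.bn_gamma[None, :, None] * inv_std[None, :, None] * dbn
    x = cache["sub"]["x"]
    grads["conv_w"] = np.tensordot(dpre_conv, x, axes=([0, 2], [0, 2]))
    grads["conv_b"] = dpre_conv.sum(axis=(0, 2))
    return grads
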