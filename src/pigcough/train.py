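"""Training: cross-entropy loss, analytic gradients, dual regularisation
(weight decay + global-norm gradient clipping), bias-corrected Adam with
stratified learning rates, and the frozen-backbone fit loop.

The update pipeline per step, applied to the flattened trainable gradient:

    g_t    = [vec(dL/dW); dL/db; ...]           (analytic backprop)
    g_reg  = g_t + lambda * [vec(W); b; ...]    (weight decay, lambda = 1e-5)
    g_clip = g_reg                 if ||g_reg|| <= tau
           = tau * g_reg/||g_reg|| otherwise    (tau = 0.3, global L2 norm)
    m_t    = b1 m_{t-1} + (1-b1) g_clip
    v_t    = b2 v_{t-1} + (1-b2) g_clip^2
    theta  = theta - alpha * (m_t/(1-b1^t)) / (sqrt(v_t/(1-b2^t)) + eps)

The TFDS branch trains at 3e-4 and the classification head at 1e-3 by
default (stratified learning rates); disabling stratification uses 3e-4 for
everything.  The backbone never enters the optimiser: gradient flow into it
is discarded at the fusion point.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .audio import ValidationError
from .model import CoughModel

logger = logging.getLogger(__name__)

PROB_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# Loss and head gradients
# ---------------------------------------------------------------------------

def cross_entropy(probs: np.ndarray, labels_onehot: np.ndarray) -> float:
    """Mean negative log-likelihood of the true class over the batch."""
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels_onehot, dtype=np.float64)
    if probs.shape != labels.shape or probs.shape[0] < 1:
        raise ValidationError("probs/labels shape mismatch or empty batch")
    p_true = (probs * labels).sum(axis=1)
    if np.any(p_true <= PROB_FLOOR):
        warnings.warn("true-class probability at or below floor; clamping",
                      RuntimeWarning, stacklevel=2)
        p_true = np.maximum(p_true, PROB_FLOOR)
    return float(-np.mean(np.log(p_true)))


def softmax_grad(probs: np.ndarray, labels_onehot: np.ndarray) -> np.ndarray:
    """dL/dz = (p - y) / K for the mean cross-entropy through softmax."""
    k = probs.shape[0]
    return (probs - labels_onehot) / k


def analytic_gradients(probs: np.ndarray, labels_onehot: np.ndarray,
                       h: np.ndarray) -> np.ndarray:
    """Flat head gradient [vec(dL/dW); dL/db] from the softmax-layer gradient.

    ``h`` is the pre-logits (post-dropout) batch, (K, D); the result has
    length 2*D + 2 (4354 under defaults).
    """
    dz = softmax_grad(probs, labels_onehot)      # (K, 2)
    dw = dz.T @ h                                # (2, D)
    db = dz.sum(axis=0)                          # (2,)
    return np.concatenate([dw.ravel(), db])


# ---------------------------------------------------------------------------
# Regularisation and optimiser
# ---------------------------------------------------------------------------

def regularize(g: np.ndarray, params_flat: np.ndarray,
               weight_decay: float) -> np.ndarray:
    """g_reg = g + lambda * theta (decay added to the gradient, not decoupled)."""
    if g.shape != params_flat.shape:
        raise ValidationError("gradient/parameter length mismatch")
    return g + weight_decay * params_flat


def clip(g: np.ndarray, tau: float) -> np.ndarray:
    """Global L2-norm clipping: rescale to norm tau when it is exceeded."""
    if tau <= 0:
        raise ValidationError("clip threshold must be positive")
    norm = float(np.linalg.norm(g))
    if norm <= tau:
        return g
    return (tau / norm) * g


@dataclass
class OptimizerState:
    m: np.ndarray
    v: np.ndarray
    step: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    alpha: float = 1e-3
    eps: float = 1e-8

    @classmethod
    def zeros(cls, n: int, alpha: float, **kw) -> "OptimizerState":
        return cls(m=np.zeros(n), v=np.zeros(n), alpha=alpha, **kw)


def adam_step(state: OptimizerState, g_clip: np.ndarray,
              params: np.ndarray) -> np.ndarray:
    """One bias-corrected Adam update; mutates ``state``, returns new params."""
    state.step += 1
    state.m = state.beta1 * state.m + (1 - state.beta1) * g_clip
    state.v = state.beta2 * state.v + (1 - state.beta2) * g_clip ** 2
    m_hat = state.m / (1 - state.beta1 ** state.step)
    v_hat = state.v / (1 - state.beta2 ** state.step)
    return params - state.alpha * m_hat / (np.sqrt(v_hat) + state.eps)


# ---------------------------------------------------------------------------
# Fit loop
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    lr_tfds: float = 3e-4
    lr_head: float = 1e-3
    uniform_lr: float = 3e-4        # used when the variant disables stratification
    weight_decay: float = 1e-5
    clip_tau: float | None = 0.3    # None disables clipping
    batch_size: int = 8
    epochs: int = 50
    eval_every: int = 5
    seed: int = 0
    early_stop_patience: int = 3    # validation checks without improvement
    decay_scope: str = "all"        # "all" or "head" (literal replication)


@dataclass
class TrainLog:
    records: list[dict] = field(default_factory=list)
    best_val_accuracy: float = float("nan")
    best_epoch: int = -1

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as f:
            w = csv.DictWriter(f, fieldnames=["epoch", "split", "loss",
                                              "accuracy"])
            w.writeheader()
            w.writerows(self.records)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"best_val_accuracy": self.best_val_accuracy,
             "best_epoch": self.best_epoch,
             "records": self.records}, indent=2))


def _flatten_group(tensors: dict[str, np.ndarray]) -> np.ndarray:
    return np.concatenate([tensors[k].ravel() for k in sorted(tensors)])


def _unflatten_group(flat: np.ndarray, template: dict[str, np.ndarray]
                     ) -> dict[str, np.ndarray]:
    out, off = {}, 0
    for k in sorted(template):
        n = template[k].size
        out[k] = flat[off:off + n].reshape(template[k].shape)
        off += n
    return out


def _accuracy(probs: np.ndarray, labels_onehot: np.ndarray) -> float:
    return float(np.mean(probs.argmax(axis=1) == labels_onehot.argmax(axis=1)))


def fit(model: CoughModel, features: np.ndarray, g14: np.ndarray | None,
        labels_onehot: np.ndarray, cfg: TrainConfig,
        val: tuple[np.ndarray, np.ndarray | None, np.ndarray] | None = None
        ) -> TrainLog:
    """Train the TFDS branch and classification head; the backbone is frozen.

    ``features`` are Log-Mel tensors (N, 64, 62); ``g14`` the matching frozen
    embeddings (precomputed once -- they cannot change during training);
    ``val`` an optional (features, g14, labels) triple scored every
    ``cfg.eval_every`` epochs.  The best-validation parameters are restored
    at the end.  Fully reproducible for a fixed ``cfg.seed``.
    """
    labels_onehot = np.asarray(labels_onehot)
    n = features.shape[0]
    if labels_onehot[:, 0].sum() == 0 or labels_onehot[:, 1].sum() == 0:
        raise ValidationError("training split must contain both classes")
    rng = np.random.default_rng(cfg.seed)
    stratified = model.variant.stratified_lr
    group_lr = {"head": cfg.lr_head if stratified else cfg.uniform_lr,
                "tfds": cfg.lr_tfds if stratified else cfg.uniform_lr,
                "proj": cfg.lr_head if stratified else cfg.uniform_lr}
    groups = model.trainable_groups()
    states = {name: OptimizerState.zeros(_flatten_group(t).size,
                                         alpha=group_lr[name])
              for name, t in groups.items()}
    log = TrainLog()
    best_params: dict | None = None
    best_state = (float("-inf"), -1)
    evals_since_best = 0
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        epoch_loss, epoch_correct = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = features[idx]
            gb = g14[idx] if g14 is not None else None
            yb = labels_onehot[idx]
            cache: dict = {}
            probs = model.forward(xb, gb, training=True, rng=rng, cache=cache)
            epoch_loss += cross_entropy(probs, yb) * idx.size
            epoch_correct += int((probs.argmax(1) == yb.argmax(1)).sum())
            grads = model.backward(yb, cache)
            groups = model.trainable_groups()
            flat_g = {name: _flatten_group(grads[name]) for name in grads}
            flat_p = {name: _flatten_group(groups[name]) for name in grads}
            # weight decay, then global-norm clipping over the concatenation
            for name in flat_g:
                if cfg.decay_scope == "all" or name == "head":
                    flat_g[name] = regularize(flat_g[name], flat_p[name],
                                              cfg.weight_decay)
            if cfg.clip_tau is not None:
                names = sorted(flat_g)
                concat = np.concatenate([flat_g[nm] for nm in names])
                concat = clip(concat, cfg.clip_tau)
                off = 0
                for nm in names:
                    sz = flat_g[nm].size
                    flat_g[nm] = concat[off:off + sz]
                    off += sz
            for name in flat_g:
                new_flat = adam_step(states[name], flat_g[name], flat_p[name])
                model.set_group(name, _unflatten_group(new_flat, groups[name]))
        log.records.append({"epoch": epoch, "split": "train",
                            "loss": epoch_loss / n,
                            "accuracy": epoch_correct / n})
        if val is not None and epoch % cfg.eval_every == 0:
            vx, vg, vy = val
            vprobs = model.forward(vx, vg, training=False)
            vacc = _accuracy(vprobs, vy)
            log.records.append({"epoch": epoch, "split": "val",
                                "loss": cross_entropy(vprobs, vy),
                                "accuracy": vacc})
            if vacc > best_state[0]:
                best_state = (vacc, epoch)
                best_params = {name: {k: v.copy() for k, v in t.items()}
                               for name, t in model.trainable_groups().items()}
                if model.variant.use_tfds:
                    best_params["_bn"] = {"mean": model.tfds.bn_mean.copy(),
                                          "var": model.tfds.bn_var.copy()}
                evals_since_best = 0
            else:
                evals_since_best += 1
                if evals_since_best >= cfg.early_stop_patience:
                    logger.info("early stop at epoch %d (best %.4f @ %d)",
                                epoch, best_state[0], best_state[1])
                    break
    if best_params is not None:
        for name, t in best_params.items():
            if name == "_bn":
                model.tfds.bn_mean = t["mean"]
                model.tfds.bn_var = t["var"]
            else:
                model.set_group(name, t)
        log.best_val_accuracy, log.best_epoch = best_state
    return log
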