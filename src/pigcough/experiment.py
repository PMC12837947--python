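"""End-to-end experiment orchestration on the synthetic corpus.

Ties the stages together the way the study runs them: generate labelled
clips, extract Log-Mel features, embed every clip once through the frozen
backbone, hold out a stratified 15% test set, train the TFDS branch and
classification head with an internal validation fold, then evaluate with
confusion metrics, calibration, AUPRC, a permutation test and stratified
5-fold cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .audio import (AudioSegment, FeatureBatch, batch_features,
                    compute_log_mel, make_mel_filterbank, normalize_duration)
from .backbone import BackboneWeights, embed_corpus, init_random
from .config import RunConfig, stage_seed
from .metrics import (PrCurve, CalibrationReport, CvResult, MetricsReport,
                      PermutationResult, confusion, basic_metrics,
                      kfold_indices, metrics_from_probs, onehot_to_int,
                      permutation_test, pr_auprc, reliability_ece,
                      stratified_split, summarize_cv)
from .model import CoughModel
from .synth import generate_segments
from .train import TrainLog, fit

logger = logging.getLogger(__name__)


def extract_features(segments: list[AudioSegment], cfg: RunConfig | None = None
                     ) -> FeatureBatch:
    """Duration-normalise and convert clips to a stacked Log-Mel batch."""
    cfg = cfg if cfg is not None else RunConfig()
    fc = cfg.features
    bank = make_mel_filterbank(fc.n_mels, fc.stft.n_fft,
                               rate=segments[0].rate, fmin=fc.fmin,
                               fmax=fc.fmax)
    specs, labels, ids = [], [], []
    for seg in segments:
        seg = normalize_duration(seg, fc.target_len, mode="center-crop")
        specs.append(compute_log_mel(seg, fc.stft, bank, fc.floor_eps,
                                     fc.log_base))
        labels.append(seg.label)
        ids.append(seg.source_id)
    return batch_features(specs, labels, ids)


def build_backbone(cfg: RunConfig, train_features: np.ndarray,
                   seed: int) -> BackboneWeights:
    """Random-initialised frozen backbone with input-normalisation statistics
    fitted once on the training features (then frozen)."""
    stats = (float(train_features.mean()), float(train_features.var()))
    return init_random(cfg.backbone, seed=seed, input_stats=stats)


@dataclass
class ExperimentResult:
    test_metrics: MetricsReport
    test_counts: "object"
    calibration: CalibrationReport
    pr: PrCurve
    permutation: PermutationResult
    cv: CvResult
    train_log: TrainLog
    model: CoughModel
    n_trainable: int
    n_test: int


def _accuracy_score(pred: np.ndarray, true: np.ndarray) -> float:
    return float(np.mean(np.asarray(pred) == np.asarray(true)))


def train_eval_once(model: CoughModel, features: np.ndarray,
                    g14: np.ndarray | None, labels: np.ndarray,
                    train_idx: np.ndarray, val_idx: np.ndarray,
                    cfg: RunConfig) -> tuple[TrainLog, np.ndarray]:
    """Fit on ``train_idx`` with ``val_idx`` as the periodic validation split;
    returns the log and validation cough probabilities."""
    g_tr = g14[train_idx] if g14 is not None else None
    g_va = g14[val_idx] if g14 is not None else None
    log = fit(model, features[train_idx], g_tr, labels[train_idx],
              cfg.training, val=(features[val_idx], g_va, labels[val_idx]))
    probs = model.forward(features[val_idx], g_va, training=False)
    return log, probs[:, 0]


def run_experiment(cfg: RunConfig | None = None,
                   run_cv: bool = True) -> ExperimentResult:
    """The full study protocol on the synthetic corpus."""
    cfg = cfg if cfg is not None else RunConfig()
    seed = cfg.run_seed
    logger.info("generating corpus (%d cough / %d noise)",
                cfg.synthesis.n_cough, cfg.synthesis.n_noise)
    segments, _ = generate_segments(
        cfg.synthesis.n_cough, cfg.synthesis.n_noise,
        cfg.synthesis.cough, cfg.synthesis.noise,
        master_seed=stage_seed(seed, "corpus"))
    batch = extract_features(segments, cfg)
    features, labels = batch.tensor, batch.labels
    y_int = onehot_to_int(labels)
    tv_idx, test_idx = stratified_split(
        y_int, cfg.evaluation.test_frac, seed=stage_seed(seed, "split"))
    weights = None
    g14 = None
    if cfg.variant.use_backbone:
        logger.info("embedding %d clips through the frozen backbone",
                    features.shape[0])
        weights = build_backbone(cfg, features[tv_idx],
                                 seed=stage_seed(seed, "backbone"))
        g14 = embed_corpus(features, weights, cfg.backbone)
    # internal validation: first stratified fold of the train-val set
    folds = kfold_indices(y_int[tv_idx], cfg.evaluation.k_folds,
                          seed=stage_seed(seed, "cv"))
    tr_rel, va_rel = folds[0]
    cfg.training.seed = stage_seed(seed, "train")
    model = CoughModel.build(cfg.variant, cfg.tfds, cfg.backbone,
                             backbone_weights=weights,
                             seed=stage_seed(seed, "init"))
    logger.info("training: %d trainable parameters", model.count_trainable())
    log, _ = train_eval_once(model, features, g14, labels,
                             tv_idx[tr_rel], tv_idx[va_rel], cfg)
    # held-out test evaluation
    g_te = g14[test_idx] if g14 is not None else None
    probs_te = model.forward(features[test_idx], g_te, training=False)
    p_cough = probs_te[:, 0]
    y_te = y_int[test_idx]
    thr = cfg.evaluation.decision_threshold
    pred_te = (p_cough >= thr).astype(int)
    counts = confusion(pred_te, y_te)
    report = basic_metrics(counts)
    calib = reliability_ece(p_cough, y_te, cfg.evaluation.calibration_bins)
    pr = pr_auprc(p_cough, y_te)
    perm = permutation_test(_accuracy_score, pred_te, y_te,
                            cfg.evaluation.n_permutations,
                            seed=stage_seed(seed, "perm"))
    cv_res = None
    if run_cv:
        def fit_and_score(tr, va) -> MetricsReport:
            m = CoughModel.build(cfg.variant, cfg.tfds, cfg.backbone,
                                 backbone_weights=weights,
                                 seed=stage_seed(seed, f"cv-init"))
            g_tr = g14[tv_idx[tr]] if g14 is not None else None
            g_va = g14[tv_idx[va]] if g14 is not None else None
            fit(m, features[tv_idx[tr]], g_tr, labels[tv_idx[tr]],
                cfg.training,
                val=(features[tv_idx[va]], g_va, labels[tv_idx[va]]))
            pv = m.forward(features[tv_idx[va]], g_va, training=False)
            return metrics_from_probs(pv[:, 0], y_int[tv_idx[va]], thr)
        cv_res = summarize_cv([fit_and_score(tr, va) for tr, va in folds])
    return ExperimentResult(
        test_metrics=report, test_counts=counts, calibration=calib, pr=pr,
        permutation=perm, cv=cv_res, train_log=log, model=model,
        n_trainable=model.count_trainable(), n_test=test_idx.size)
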