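"""Evaluation framework: confusion metrics, stratified splitting, k-fold CV
with t-based confidence intervals, the permutation significance test,
calibration (reliability bins / ECE) and the precision-recall curve (AUPRC).

Throughout, integer labels use 1 = cough (the positive, minority class) and
0 = noise; probabilities refer to the cough class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .audio import ValidationError

logger = logging.getLogger(__name__)


def onehot_to_int(labels_onehot: np.ndarray) -> np.ndarray:
    """One-hot rows [cough, noise] -> integer labels with cough = 1."""
    return np.asarray(labels_onehot)[:, 0].astype(int)


# ---------------------------------------------------------------------------
# Confusion-based metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1}


def confusion(pred_labels: np.ndarray, true_labels: np.ndarray
              ) -> ConfusionCounts:
    """Counts with cough (1) as the positive class."""
    pred = np.asarray(pred_labels).astype(int)
    true = np.asarray(true_labels).astype(int)
    if pred.shape != true.shape:
        raise ValidationError("prediction/label length mismatch")
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (true == 1))),
        tn=int(np.sum((pred == 0) & (true == 0))),
        fp=int(np.sum((pred == 1) & (true == 0))),
        fn=int(np.sum((pred == 0) & (true == 1))))


def basic_metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, recall and F1 = 2TP / (2TP + FP + FN).

    Undefined 0/0 ratios are reported as 0 with a log warning.
    """
    if c.total == 0:
        raise ValidationError("no samples to evaluate")
    acc = (c.tp + c.tn) / c.total
    if c.tp + c.fp == 0:
        logger.warning("precision undefined (no positive predictions); using 0")
        prec = 0.0
    else:
        prec = c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        logger.warning("recall undefined (no positive samples); using 0")
        rec = 0.0
    else:
        rec = c.tp / (c.tp + c.fn)
    f1 = 2 * c.tp / (2 * c.tp + c.fp + c.fn) if c.tp > 0 else 0.0
    return MetricsReport(acc, prec, rec, f1)


def metrics_from_probs(probs: np.ndarray, true_labels: np.ndarray,
                       threshold: float = 0.5) -> MetricsReport:
    pred = (np.asarray(probs) >= threshold).astype(int)
    return basic_metrics(confusion(pred, true_labels))


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------

def stratified_split(labels: np.ndarray, test_frac: float = 0.15,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train-val / test index split.

    The test count is the nearest integer to ``test_frac * n``; per-class
    counts are allocated by largest remainder so class proportions are
    preserved within one sample.
    """
    labels = np.asarray(labels).astype(int)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValidationError("both classes must be present")
    if np.any(counts < 2):
        raise ValidationError("every class needs at least 2 members")
    n = labels.size
    n_test = int(round(test_frac * n))
    exact = counts * test_frac
    base = np.floor(exact).astype(int)
    remainder = exact - base
    short = n_test - base.sum()
    order = np.argsort(-remainder)
    for i in range(int(short)):
        base[order[i % classes.size]] += 1
    rng = np.random.default_rng(seed)
    test_idx = []
    for cls, take in zip(classes, base):
        members = np.flatnonzero(labels == cls)
        test_idx.append(rng.permutation(members)[:take])
    test_idx = np.sort(np.concatenate(test_idx))
    mask = np.ones(n, dtype=bool)
    mask[test_idx] = False
    return np.flatnonzero(mask), test_idx


# ---------------------------------------------------------------------------
# k-fold cross-validation with t-based confidence intervals
# ---------------------------------------------------------------------------

@dataclass
class CvResult:
    folds: list[MetricsReport]
    mean: dict[str, float] = field(default_factory=dict)
    std: dict[str, float] = field(default_factory=dict)
    ci_low: dict[str, float] = field(default_factory=dict)
    ci_high: dict[str, float] = field(default_factory=dict)


def t_confidence_interval(scores: np.ndarray, confidence: float = 0.95
                          ) -> tuple[float, float, float, float]:
    """(mean, sd, lo, hi): two-sided t interval, df = k - 1, SE = s / sqrt(k)."""
    scores = np.asarray(scores, dtype=np.float64)
    k = scores.size
    mean = float(scores.mean())
    if k < 2:
        return mean, 0.0, mean, mean
    s = float(scores.std(ddof=1))
    t_crit = float(stats.t.ppf(0.5 + confidence / 2, df=k - 1))
    half = t_crit * s / np.sqrt(k)
    return mean, s, mean - half, mean + half


def kfold_indices(labels: np.ndarray, k: int = 5, seed: int = 0
                  ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold (train_idx, val_idx) pairs; folds are mutually
    exclusive, exhaustive, and class-balanced within one sample."""
    labels = np.asarray(labels).astype(int)
    _, counts = np.unique(labels, return_counts=True)
    if np.any(counts < k):
        raise ValidationError(f"every class needs >= k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, va) for tr, va in skf.split(np.zeros(labels.size), labels)]


def summarize_cv(folds: list[MetricsReport]) -> CvResult:
    res = CvResult(folds=folds)
    for key in ("accuracy", "precision", "recall", "f1"):
        vals = np.array([getattr(f, key) for f in folds])
        mean, s, lo, hi = t_confidence_interval(vals)
        res.mean[key], res.std[key] = mean, s
        res.ci_low[key], res.ci_high[key] = lo, hi
    return res


def kfold_cv(labels: np.ndarray, fit_and_score, k: int = 5,
             seed: int = 0) -> CvResult:
    """Run ``fit_and_score(train_idx, val_idx) -> MetricsReport`` per fold and
    summarise with mean, sd and a 95% t interval."""
    folds = [fit_and_score(tr, va) for tr, va in kfold_indices(labels, k, seed)]
    return summarize_cv(folds)


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    s_true: float
    s_perm: np.ndarray
    p_value: float
    n_permutations: int


def permutation_test(score_fn, predictions: np.ndarray,
                     true_labels: np.ndarray, n_permutations: int = 100,
                     seed: int = 0) -> PermutationResult:
    """Label-shuffle significance test with p = (#{S_perm >= S_true} + 1) / (N + 1).

    The fixed predictions are rescored against permuted labels; with N
    permutations the smallest attainable p is 1 / (N + 1).
    """
    if n_permutations < 1:
        raise ValidationError("need at least one permutation")
    true = np.asarray(true_labels)
    if np.unique(true).size < 2:
        raise ValidationError("labels are constant; permutation test undefined")
    s_true = float(score_fn(predictions, true))
    rng = np.random.default_rng(seed)
    s_perm = np.array([float(score_fn(predictions, rng.permutation(true)))
                       for _ in range(n_permutations)])
    p = (int(np.sum(s_perm >= s_true)) + 1) / (n_permutations + 1)
    return PermutationResult(s_true, s_perm, p, n_permutations)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationReport:
    bin_edges: np.ndarray
    bin_accuracy: np.ndarray
    bin_confidence: np.ndarray
    bin_counts: np.ndarray
    ece: float


def reliability_ece(p_cough: np.ndarray, true_labels: np.ndarray,
                    m_bins: int = 10) -> CalibrationReport:
    """Equal-width binning of the cough probability.

    ``acc(B_m)`` is the empirical cough fraction in the bin, ``conf(B_m)``
    the mean predicted probability; ECE is the count-weighted mean absolute
    gap.  A probability on a bin's right edge falls in the lower bin except
    1.0, which belongs to the top bin.
    """
    p = np.asarray(p_cough, dtype=np.float64)
    y = np.asarray(true_labels).astype(int)
    if p.size == 0:
        raise ValidationError("empty input")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("probabilities must lie in [0, 1]")
    idx = np.ceil(p * m_bins).astype(int) - 1
    idx[p == 0.0] = 0
    idx = np.clip(idx, 0, m_bins - 1)
    counts = np.bincount(idx, minlength=m_bins)
    acc = np.zeros(m_bins)
    conf = np.zeros(m_bins)
    for m in range(m_bins):
        in_bin = idx == m
        if counts[m]:
            acc[m] = y[in_bin].mean()
            conf[m] = p[in_bin].mean()
    weights = counts / p.size
    ece = float(np.sum(weights * np.abs(acc - conf)))
    return CalibrationReport(np.linspace(0, 1, m_bins + 1), acc, conf,
                             counts, ece)


# ---------------------------------------------------------------------------
# Precision-recall curve
# ---------------------------------------------------------------------------

@dataclass
class PrCurve:
    recall: np.ndarray
    precision: np.ndarray
    thresholds: np.ndarray
    auprc: float


def pr_auprc(scores: np.ndarray, true_labels: np.ndarray) -> PrCurve:
    """Precision-recall points over all score thresholds and the step-wise
    (average-precision) area -- no trapezoidal interpolation.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(true_labels).astype(int)
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == y.size:
        raise ValidationError("both classes required for a PR curve")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    # collapse ties: keep the last index of each distinct score
    distinct = np.flatnonzero(np.diff(s_sorted, append=-np.inf))
    tp, fp, thr = tp[distinct], fp[distinct], s_sorted[distinct]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    ap = float(np.sum(np.diff(recall, prepend=0.0) * precision))
    return PrCurve(recall, precision, thr, ap)


# ---------------------------------------------------------------------------
# Plot rendering (optional)
# ---------------------------------------------------------------------------

def plot_reliability(report: CalibrationReport, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    centers = (report.bin_edges[:-1] + report.bin_edges[1:]) / 2
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot([0, 1], [0, 1], "k--", lw=1, label="perfect")
    nz = report.bin_counts > 0
    ax.bar(centers[nz], report.bin_accuracy[nz], width=0.08, alpha=0.7,
           label="empirical")
    ax.set_xlabel("predicted cough probability")
    ax.set_ylabel("empirical cough fraction")
    ax.set_title(f"Reliability diagram (ECE = {report.ece:.4f})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_pr_curve(curve: PrCurve, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.step(curve.recall, curve.precision, where="post")
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_ylim(0, 1.05)
    ax.set_title(f"PR curve (AUPRC = {curve.auprc:.4f})")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
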