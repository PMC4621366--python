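"""Performance metrics for a consciousness index.

Mean absolute error (MAE +/- SD) against the clinician reference,
per-patient Pearson correlation, and ROC/AUC for discriminating
conscious from unconscious states.  The positive (detected) class is
*unconscious*: reference index <= threshold.  Thresholds either come
from the BIS literature (48.8 = mean BIS during unconsciousness; 70 =
lowest conscious value, 89.5 mean conscious, 97 highest) or are derived
from training targets as mean + k * SD for k in {1, 1.5, 2}.

All SDs here are sample SDs (n - 1 denominator).  The ROC curve is
built by hand (threshold sweep + trapezoid) because the AUC statistic
itself is under test against a concordance-count oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BIS_UNCONSCIOUS_MEAN",
    "BIS_CONSCIOUS_LOWEST",
    "EvaluationConfig",
    "MetricsRecord",
    "mae",
    "per_patient_correlation",
    "roc_curve_points",
    "roc_auc",
    "consciousness_auc",
    "derive_thresholds",
    "aggregate_fold_mae",
    "evaluate_patient",
]

# BIS-referenced consciousness constants (configuration, not computed)
BIS_UNCONSCIOUS_MEAN = 48.8
BIS_CONSCIOUS_LOWEST = 70.0
BIS_CONSCIOUS_MEAN = 89.5
BIS_CONSCIOUS_HIGHEST = 97.0


@dataclass(frozen=True)
class EvaluationConfig:
    reference_threshold: float = BIS_UNCONSCIOUS_MEAN
    threshold_multipliers: tuple[float, ...] = (1.0, 1.5, 2.0)

    def __post_init__(self) -> None:
        if not 0 < self.reference_threshold < 100:
            raise ValueError("reference_threshold must lie in (0, 100)")


def mae(pred: np.ndarray, ref: np.ndarray) -> tuple[float, float]:
    """Mean and sample SD of the absolute errors |pred - ref|."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError("pred and ref must have equal length")
    if pred.size == 0:
        raise ValueError("need at least one sample")
    err = np.abs(pred - ref)
    sd = float(err.std(ddof=1)) if err.size > 1 else 0.0
    return float(err.mean()), sd


def per_patient_correlation(pred: np.ndarray, ref: np.ndarray) -> float:
    """Pearson r for one patient; NaN sentinel if either series is
    constant (r is undefined there)."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.size != ref.size or pred.size < 3:
        raise ValueError("need equal-length series with >= 3 rows")
    if pred.std() == 0 or ref.std() == 0:
        return float("nan")
    return float(np.corrcoef(pred, ref)[0, 1])


def roc_curve_points(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ROC curve by sweeping the decision threshold over unique scores.

    Higher score = more positive.  Returns (fpr, tpr, thresholds) with a
    leading (0, 0) point; tied scores collapse into one step so the
    trapezoid area handles ties as half-concordances.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # collapse runs of tied scores
    distinct = np.nonzero(np.diff(s))[0]
    idx = np.r_[distinct, s.size - 1]
    tp = np.cumsum(y)[idx]
    fp = np.cumsum(~y)[idx]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, s[idx]]
    return fpr, tpr, thresholds


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Trapezoid area under the ROC curve."""
    fpr, tpr, _ = roc_curve_points(scores, labels)
    return float(np.trapezoid(tpr, fpr))


def consciousness_auc(
    pred: np.ndarray,
    ref: np.ndarray,
    threshold: float,
    positive: str = "unconscious",
) -> float:
    """AUC for detecting (un)consciousness from the predicted index.

    Labels come from the reference index: unconscious = ref <=
    threshold.  For the default orientation a *lower* predicted index
    argues for the positive class, so the score is 100 - pred.
    """
    ref = np.asarray(ref, dtype=float)
    pred = np.asarray(pred, dtype=float)
    unconscious = ref <= threshold
    if positive == "unconscious":
        return roc_auc(100.0 - pred, unconscious)
    if positive == "conscious":
        return roc_auc(pred, ~unconscious)
    raise ValueError("positive must be 'unconscious' or 'conscious'")


def derive_thresholds(
    training_targets: np.ndarray,
    multipliers: tuple[float, ...] = (1.0, 1.5, 2.0),
) -> dict[float, float]:
    """Thresholds mean + k * SD of the training targets, kept in (0, 100)."""
    t = np.asarray(training_targets, dtype=float)
    if t.size < 2:
        raise ValueError("need >= 2 training targets")
    sd = float(t.std(ddof=1))
    if sd == 0:
        raise ValueError("constant training targets give no spread")
    m = float(t.mean())
    eps = 1e-9
    return {float(k): float(np.clip(m + k * sd, eps, 100.0 - eps)) for k in multipliers}


def aggregate_fold_mae(fold_maes: np.ndarray) -> tuple[float, float]:
    """Mean and sample SD over per-fold MAE values (the cross-validation
    summary row)."""
    m = np.asarray(fold_maes, dtype=float)
    if m.size < 2:
        raise ValueError("need >= 2 folds")
    return float(m.mean()), float(m.std(ddof=1))


@dataclass
class MetricsRecord:
    """Per-patient evaluation summary."""

    mae: float
    mae_sd: float
    pearson_r: float
    auc_by_threshold: dict[float, float] = field(default_factory=dict)
    n_rows: int = 0


def evaluate_patient(
    pred: np.ndarray,
    ref: np.ndarray,
    thresholds: dict[float, float] | None = None,
) -> MetricsRecord:
    """MAE, correlation and per-threshold AUC for one patient.

    Thresholds for which only one class occurs in the reference yield a
    NaN AUC rather than an error.
    """
    m, sd = mae(pred, ref)
    r = per_patient_correlation(pred, ref)
    aucs: dict[float, float] = {}
    for key, thr in (thresholds or {0.0: BIS_UNCONSCIOUS_MEAN}).items():
        try:
            aucs[key] = consciousness_auc(pred, ref, thr)
        except ValueError:
            aucs[key] = float("nan")
    return MetricsRecord(
        mae=m, mae_sd=sd, pearson_r=r, auc_by_threshold=aucs, n_rows=len(np.asarray(pred))
    )
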