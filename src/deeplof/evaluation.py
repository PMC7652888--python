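"""ROC / precision-recall evaluation with confidence intervals.

Point metrics are ROC-AUC, PR-AUC (average precision, the step-wise
non-interpolated rule) and the sensitivity/specificity pair at the
Youden-index operating point.  Uncertainty comes from a class-stratified
case-resampling bootstrap (percentile 95% intervals) for sensitivity,
specificity and PR-AUC, and from the DeLong structural-components
estimator for the ROC-AUC variance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve as _sk_roc_curve

__all__ = [
    "ScoredLabelSet",
    "EvalReport",
    "roc_auc",
    "pr_auc",
    "youden_threshold",
    "bootstrap_ci",
    "delong_ci",
    "delong_variance",
    "build_report",
    "roc_curve_points",
    "pr_curve_points",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric is requested on a degenerate label set."""


@dataclass(frozen=True)
class ScoredLabelSet:
    """Scores with binary labels (1 = abnormal/positive)."""

    scores: np.ndarray
    labels: np.ndarray
    case_ids: tuple[str, ...] | None = None

    def __post_init__(self):
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=np.float64))
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=int))
        if self.scores.shape != self.labels.shape or self.scores.ndim != 1:
            raise ValueError("scores and labels must be 1-D and equal length")
        if not np.all(np.isin(self.labels, (0, 1))):
            raise ValueError("labels must be binary (0/1)")

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int(len(self.labels) - self.labels.sum())


def _require_both_classes(s: ScoredLabelSet) -> None:
    if s.n_pos == 0 or s.n_neg == 0:
        raise UndefinedMetricError("metric undefined: need both classes present")


def roc_auc(s: ScoredLabelSet) -> float:
    """Area under the ROC curve (equals the Mann-Whitney pair-counting
    statistic, ties counted half)."""
    _require_both_classes(s)
    return float(roc_auc_score(s.labels, s.scores))


def pr_auc(s: ScoredLabelSet) -> float:
    """Average precision: the step-wise area under the precision-recall
    curve (no linear interpolation between operating points)."""
    if s.n_pos == 0:
        raise UndefinedMetricError("PR metrics need at least one positive")
    return float(average_precision_score(s.labels, s.scores))


def _sens_spec_at(s: ScoredLabelSet, threshold: float) -> tuple[float, float]:
    decisions = s.scores > threshold
    sens = float(decisions[s.labels == 1].mean())
    spec = float((~decisions[s.labels == 0]).mean())
    return sens, spec


def youden_threshold(s: ScoredLabelSet) -> tuple[float, float, float]:
    """Operating point maximizing J = sensitivity + specificity - 1.

    Candidate thresholds are the midpoints between adjacent distinct
    scores plus -inf/+inf sentinels; the decision rule is score >
    threshold.  Ties on J resolve toward the higher sensitivity (the
    lower threshold).  Returns (threshold, sensitivity, specificity).
    """
    _require_both_classes(s)
    uniq = np.unique(s.scores)
    candidates = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]))
    best = None
    for thr in candidates:
        sens, spec = _sens_spec_at(s, thr)
        j = sens + spec - 1.0
        # strictly-better J, or equal J with strictly-better sensitivity
        if best is None or j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and sens > best[1]):
            best = (j, sens, spec, thr)
    _, sens, spec, thr = best
    return float(thr), sens, spec


def bootstrap_ci(s: ScoredLabelSet, metric_fn, n_boot: int = 2000,
                 seed: int = 0) -> tuple[float, float]:
    """Percentile 95% interval from a class-stratified case-resampling
    bootstrap.  Stratification guarantees both classes survive each
    resample; a resample on which the metric still fails is redrawn."""
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    metric_fn(s)  # must be defined on the original set
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(s.labels == 1)
    neg = np.flatnonzero(s.labels == 0)
    values = np.empty(n_boot)
    i = 0
    while i < n_boot:
        idx = np.concatenate([rng.choice(pos, size=len(pos), replace=True),
                              rng.choice(neg, size=len(neg), replace=True)])
        try:
            values[i] = metric_fn(ScoredLabelSet(s.scores[idx], s.labels[idx]))
        except UndefinedMetricError:
            continue
        i += 1
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float(lo), float(hi)


def _placement_components(s: ScoredLabelSet) -> tuple[np.ndarray, np.ndarray]:
    x = s.scores[s.labels == 1]
    y = s.scores[s.labels == 0]
    # V10_i: placement of positive i among negatives; V01_j symmetric
    gt = (x[:, None] > y[None, :]).astype(float)
    eq = (x[:, None] == y[None, :]).astype(float)
    mat = gt + 0.5 * eq
    return mat.mean(axis=1), mat.mean(axis=0)


def delong_variance(s: ScoredLabelSet) -> float:
    """DeLong variance of the ROC-AUC from the structural components:
    var = S10/m + S01/n with S10, S01 the sample variances of the
    positive- and negative-side placement values."""
    _require_both_classes(s)
    if s.n_pos < 2 or s.n_neg < 2:
        raise UndefinedMetricError("DeLong variance needs >= 2 cases per class")
    v10, v01 = _placement_components(s)
    return float(v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01))


def delong_ci(s: ScoredLabelSet, level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """ROC-AUC with its DeLong normal-approximation confidence interval,
    clipped to [0, 1].  The point estimate is identical to :func:`roc_auc`."""
    auc = roc_auc(s)
    se = math.sqrt(delong_variance(s))
    from scipy.stats import norm
    z = norm.ppf(0.5 + level / 2.0)
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    return auc, (lo, hi)


@dataclass
class EvalReport:
    """Per-method evaluation summary: the four headline metrics plus 95%
    confidence intervals (DeLong for ROC-AUC, bootstrap otherwise)."""

    roc_auc: float
    pr_auc: float
    sensitivity: float
    specificity: float
    threshold: float
    ci_roc_auc: tuple[float, float]
    ci_pr_auc: tuple[float, float]
    ci_sens: tuple[float, float]
    ci_spec: tuple[float, float]
    n_bootstrap: int
    seed: int
    threshold_source: str = "test_youden"

    def to_dict(self) -> dict:
        d = asdict(self)
        if not math.isfinite(d["threshold"]):
            d["threshold"] = str(d["threshold"])
        return d

    def to_json(self, path: str | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "EvalReport":
        d = dict(d)
        if isinstance(d["threshold"], str):
            d["threshold"] = float(d["threshold"])
        for key in ("ci_roc_auc", "ci_pr_auc", "ci_sens", "ci_spec"):
            d[key] = tuple(d[key])
        return cls(**d)


def build_report(s: ScoredLabelSet, n_boot: int = 2000, seed: int = 0) -> EvalReport:
    """Assemble the full evaluation report for one scored test set.

    Sensitivity/specificity intervals are bootstrapped with the operating
    threshold held fixed at the full-sample Youden point.
    """
    thr, sens, spec = youden_threshold(s)
    auc, ci_auc = delong_ci(s)
    ap = pr_auc(s)
    ci_ap = bootstrap_ci(s, pr_auc, n_boot=n_boot, seed=seed)
    ci_sens = bootstrap_ci(s, lambda t: _sens_spec_at(t, thr)[0], n_boot=n_boot, seed=seed + 1)
    ci_spec = bootstrap_ci(s, lambda t: _sens_spec_at(t, thr)[1], n_boot=n_boot, seed=seed + 2)
    return EvalReport(auc, ap, sens, spec, thr, ci_auc, ci_ap, ci_sens, ci_spec,
                      n_boot, seed)


def roc_curve_points(s: ScoredLabelSet) -> pd.DataFrame:
    fpr, tpr, thr = _sk_roc_curve(s.labels, s.scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def pr_curve_points(s: ScoredLabelSet) -> pd.DataFrame:
    from sklearn.metrics import precision_recall_curve
    prec, rec, thr = precision_recall_curve(s.labels, s.scores)
    return pd.DataFrame({"precision": prec, "recall": rec,
                         "threshold": np.append(thr, np.nan)})
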