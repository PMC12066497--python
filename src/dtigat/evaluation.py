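"""Metric suite, cross-validation aggregation and ablation comparisons.

Metrics follow the standard confusion-matrix definitions (accuracy,
sensitivity, specificity, precision, Matthews correlation) at a threshold
chosen on the validation split by maximizing Youden's J, plus ROC-AUC as
the Mann-Whitney rank statistic (ties counted half) and the area under
the step-wise precision-recall curve (no linear interpolation of
precision). Any metric with a zero denominator is reported as 0 and
flagged rather than raising, so tiny-fold ablation runs never crash.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from scipy.stats import rankdata


class UndefinedMetricError(ValueError):
    """Metric undefined for this input (e.g. single-class AUC)."""


def _check_labels(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels)
    if y.size == 0:
        raise ValueError("at least one sample required")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be in {0, 1}")
    return y.astype(int)


@dataclass(frozen=True)
class ConfusionMetrics:
    acc: float
    sen: float
    spec: float
    pre: float
    mcc: float
    flagged: tuple[str, ...] = ()  # metrics forced to 0 by a zero denominator

    def as_dict(self) -> dict[str, float]:
        return {"Acc": self.acc, "Sen": self.sen, "Spec": self.spec,
                "Pre": self.pre, "MCC": self.mcc}


def confusion_metrics(labels: np.ndarray, scores: np.ndarray, threshold: float) -> ConfusionMetrics:
    """Acc/Sen/Spec/Pre/MCC at ``threshold`` (score >= threshold is positive)."""
    y = _check_labels(labels)
    pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    flagged = []

    def safe(num: float, den: float, name: str) -> float:
        if den == 0:
            flagged.append(name)
            return 0.0
        return num / den

    acc = (tp + tn) / len(y)
    sen = safe(tp, tp + fn, "Sen")
    spec = safe(tn, tn + fp, "Spec")
    pre = safe(tp, tp + fp, "Pre")
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = safe(tp * tn - fp * fn, mcc_den, "MCC")
    return ConfusionMetrics(acc=acc, sen=sen, spec=spec, pre=pre, mcc=mcc,
                            flagged=tuple(flagged))


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie), by mid-ranks."""
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC-AUC needs both classes present")
    ranks = rankdata(s)  # mid-ranks: ties share the average rank
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def pr_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the step-wise precision-recall curve.

    Thresholds sweep the distinct score values from high to low;
    contribution at each step is (recall_i - recall_{i-1}) * precision_i,
    with no linear interpolation of precision.
    """
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise UndefinedMetricError("PR-AUC needs at least one positive")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    # keep only the last index of each tied score block (complete threshold)
    last = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tp, fp = tp[last], fp[last]
    recall = tp / n_pos
    precision = tp / (tp + fp)
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def youden_threshold(labels: np.ndarray, scores: np.ndarray) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1 on the
    given (validation) split; evaluated at every distinct score."""
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    best_t, best_j = 0.5, -np.inf
    for t in np.unique(s):
        m = confusion_metrics(y, s, t)
        j = m.sen + m.spec - 1.0
        if j > best_j:
            best_j, best_t = j, float(t)
    return best_t


# ---------------------------------------------------------------------------
# Cross-validation reports
# ---------------------------------------------------------------------------

REPORT_COLUMNS = ["Acc", "Sen", "Spec", "Pre", "MCC", "AUC", "AUPR"]


@dataclass
class EvalReport:
    """Per-fold metric rows plus mean +/- SD, and cold-start subset metrics."""

    fold_rows: list[dict] = field(default_factory=list)
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)
    cold: dict | None = None  # pooled cold-start subset metrics, if non-empty

    def finalize(self) -> "EvalReport":
        for col in REPORT_COLUMNS:
            vals = np.array([row[col] for row in self.fold_rows], dtype=float)
            self.mean[col] = float(vals.mean())
            self.sd[col] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        return self

    @property
    def n_rows(self) -> int:
        """Fold rows + the average row, mirroring the CV report layout."""
        return len(self.fold_rows) + 1

    def to_text(self) -> str:
        lines = ["Fold\t" + "\t".join(REPORT_COLUMNS)]
        for row in self.fold_rows:
            lines.append(str(row["Fold"]) + "\t" +
                         "\t".join(f"{row[c]:.4f}" for c in REPORT_COLUMNS))
        lines.append("Average\t" + "\t".join(
            f"{self.mean[c]:.4f} ± {self.sd[c]:.4f}" for c in REPORT_COLUMNS))
        if self.cold is not None:
            lines.append("# cold-start subset (pooled over folds): " + ", ".join(
                f"{k}={v:.4f}" if isinstance(v, float) else f"{k}={v}"
                for k, v in self.cold.items()))
        return "\n".join(lines) + "\n"

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(self.to_text())


def evaluate_fold(trained, fold) -> dict:
    """Test-split metrics for one fold; threshold picked on validation."""
    model = trained.model
    val_scores = model.forward_scores(fold.val_pairs)
    threshold = youden_threshold(fold.val_labels, val_scores)
    test_scores = model.forward_scores(fold.test_pairs)
    cm = confusion_metrics(fold.test_labels, test_scores, threshold)
    row = {"Fold": fold.fold_index + 1, **cm.as_dict(),
           "AUC": roc_auc(fold.test_labels, test_scores),
           "AUPR": pr_auc(fold.test_labels, test_scores),
           "threshold": threshold}
    row["_scores"] = test_scores
    return row


def evaluate_cv(trained_models: list, folds: list) -> EvalReport:
    """Per-fold metrics, mean +/- SD row, and pooled cold-start metrics."""
    if len(trained_models) != len(folds):
        raise ValueError(f"{len(trained_models)} models for {len(folds)} folds")
    report = EvalReport()
    cold_scores, cold_labels = [], []
    for tm, fold in zip(trained_models, folds):
        row = evaluate_fold(tm, fold)
        scores = row.pop("_scores")
        report.fold_rows.append(row)
        mask = fold.test_cold
        if mask.any():
            cold_scores.append(scores[mask])
            cold_labels.append(fold.test_labels[mask])
    report.finalize()
    if cold_scores:
        cs = np.concatenate(cold_scores)
        cl = np.concatenate(cold_labels)
        cold: dict = {"n": int(len(cl)), "n_pos": int(cl.sum())}
        if 0 < cl.sum() < len(cl):
            cold["AUC"] = roc_auc(cl, cs)
            cold["AUPR"] = pr_auc(cl, cs)
        report.cold = cold
    return report


# ---------------------------------------------------------------------------
# Ablations
# ---------------------------------------------------------------------------

ABLATION_VARIANTS = ("full", "no_attention", "no_attributes")


def run_ablations(
    synth_config,
    model_config=None,
    train_config=None,
    k: int = 5,
    fold_subset: list[int] | None = None,
    variants: tuple[str, ...] = ABLATION_VARIANTS,
) -> dict[str, dict]:
    """Train and evaluate {full, no-attention (GCN), no-attributes} under
    identical worlds, folds and seeds.

    Returns per-variant: the EvalReport, pooled cold-start metrics, and
    the learned view fusion weights alpha (mean over trained folds).
    ``variants`` restricts the comparison to a subset of the three.
    """
    from .training import TrainConfig, run_cv

    tc = train_config or TrainConfig()
    switches = {
        "full": {},
        "no_attention": {"use_attention": False},
        "no_attributes": {"use_attributes": False},
    }
    unknown = set(variants) - set(ABLATION_VARIANTS)
    if unknown:
        raise ValueError(f"unknown ablation variants: {sorted(unknown)}")
    results: dict[str, dict] = {}
    for variant in variants:
        cv = run_cv(synth_config, model_config, dc_replace(tc, **switches[variant]),
                    k=k, fold_subset=fold_subset)
        report = evaluate_cv(cv.trained, cv.folds)
        alphas = np.stack([tm.model.fusion_alpha() for tm in cv.trained])
        results[variant] = {
            "report": report,
            "auc": report.mean["AUC"],
            "aupr": report.mean["AUPR"],
            "cold": report.cold,
            "fusion_alpha": alphas.mean(axis=0),
            "view_names": cv.view_names,
        }
    return results
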