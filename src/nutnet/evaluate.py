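"""Metrics, confusion matrices, failure summaries, stratified k-fold
statistics and paired t-tests.

Definitions (per class c, from the confusion matrix): precision
TP/(TP+FP), recall = sensitivity TP/(TP+FN), specificity TN/(TN+FP), F1 the
harmonic mean of precision and recall, and IoU (Jaccard) TP/(TP+FP+FN).
Macro values are unweighted class means; zero-denominator cases are
reported as 0 and flagged.  All proportions are reported as percentages.

The failure table mirrors the common reporting convention in which the
"total" error rate is the unweighted mean of per-class error rates — note
this differs from total-misclassified / total-samples, and both are
exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold


def confusion(y_true, y_pred, n_classes: int) -> np.ndarray:
    """counts[i, j] = #(true == i, predicted == j)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    for v in (y_true, y_pred):
        if v.size and (v.min() < 0 or v.max() >= n_classes):
            raise ValueError("labels out of range")
    return _sk_confusion(y_true, y_pred, labels=np.arange(n_classes))


@dataclass
class MetricsReport:
    per_class: pd.DataFrame        # percentages per class
    macro: dict[str, float]        # unweighted means, percentages
    accuracy: float                # trace/total, percentage
    zero_denominator_flags: list[str] = field(default_factory=list)


def metrics_from_confusion(cm: np.ndarray) -> MetricsReport:
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    n = cm.shape[0]
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = total - tp - fp - fn
    flags = []

    def safe(num, den, name):
        out = np.zeros(n)
        for c in range(n):
            if den[c] == 0:
                flags.append(f"{name}: class {c} has zero denominator")
            else:
                out[c] = num[c] / den[c]
        return out

    precision = safe(tp, tp + fp, "precision")
    recall = safe(tp, tp + fn, "recall")
    specificity = safe(tn, tn + fp, "specificity")
    iou = safe(tp, tp + fp + fn, "iou")
    f1 = np.zeros(n)
    for c in range(n):
        if precision[c] + recall[c] > 0:
            f1[c] = 2 * precision[c] * recall[c] / (precision[c] + recall[c])
        else:
            flags.append(f"f1: class {c} degenerate")
    per_class = pd.DataFrame({
        "precision": precision * 100, "recall": recall * 100,
        "sensitivity": recall * 100, "specificity": specificity * 100,
        "f1": f1 * 100, "iou": iou * 100,
    })
    macro = {k: float(per_class[k].mean()) for k in per_class.columns}
    accuracy = float(tp.sum() / total * 100)
    macro["accuracy"] = accuracy
    return MetricsReport(per_class, macro, accuracy, flags)


def failure_summary(cm: np.ndarray, class_names) -> pd.DataFrame:
    """Per-class misclassification table plus a totals row.

    The totals row aggregates sample/misclassified counts; its error-rate
    cell is the unweighted mean of the per-class error rates (the
    aggregate misclassified/total rate is reported alongside it).
    """
    cm = np.asarray(cm)
    row_sums = cm.sum(axis=1)
    mis = row_sums - np.diag(cm)
    rate = np.where(row_sums > 0, mis / np.maximum(row_sums, 1) * 100, 0.0)
    df = pd.DataFrame({
        "class": list(class_names),
        "testing_samples": row_sums,
        "misclassified": mis,
        "error_rate_pct": np.round(rate, 2),
    })
    totals = {
        "class": "total",
        "testing_samples": int(row_sums.sum()),
        "misclassified": int(mis.sum()),
        "error_rate_pct": round(float(np.round(rate, 2).mean()), 2),
    }
    df = pd.concat([df, pd.DataFrame([totals])], ignore_index=True)
    df.attrs["aggregate_error_rate_pct"] = (
        float(mis.sum() / row_sums.sum() * 100) if row_sums.sum() else 0.0)
    return df


@dataclass
class FoldStats:
    values: np.ndarray             # per-fold metric values
    mean: float
    sd: float                      # sample standard deviation (ddof=1)
    ci95_t: tuple[float, float]    # Student-t multiplier, df = k-1
    ci95_normal: tuple[float, float]

    @classmethod
    def from_values(cls, values) -> "FoldStats":
        v = np.asarray(values, dtype=float)
        k = len(v)
        mean = float(v.mean())
        sd = float(v.std(ddof=1)) if k > 1 else 0.0
        se = sd / np.sqrt(k) if k else 0.0
        tmult = stats.t.ppf(0.975, k - 1) if k > 1 else 0.0
        zmult = stats.norm.ppf(0.975)
        return cls(v, mean, sd,
                   (mean - tmult * se, mean + tmult * se),
                   (mean - zmult * se, mean + zmult * se))


@dataclass
class PairedTTest:
    mean_difference: float
    t: float | None
    p: float | None
    df: int
    degenerate: bool = False

    def p_formatted(self) -> str:
        if self.degenerate:
            return "n/a"
        return "< 0.0001" if self.p < 1e-4 else f"{self.p:.4f}"


def paired_ttest(metric_a, metric_b) -> PairedTTest:
    """Two-tailed paired Student t-test on per-fold metric vectors.

    Zero-variance differences are reported as degenerate (t undefined)
    rather than infinite.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("fold vectors must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 folds")
    d = a - b
    mean_diff = float(d.mean())
    if np.allclose(d.std(ddof=1), 0.0):
        return PairedTTest(mean_diff, None, None, len(d) - 1, degenerate=True)
    res = stats.ttest_rel(a, b)
    return PairedTTest(mean_diff, float(res.statistic), float(res.pvalue),
                       len(d) - 1)


def kfold_cv(x, y, k: int, train_eval_fn, seed: int = 0) -> dict:
    """Stratified k-fold CV over a (non-test) dataset.

    ``train_eval_fn(x_tr, y_tr, x_ho, y_ho) -> dict of metric -> value``
    is called once per fold; returns per-metric FoldStats.  Classes with
    fewer than k members are an error.
    """
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    _, counts = np.unique(y, return_counts=True)
    if counts.size and counts.min() < k:
        raise ValueError(f"every class needs >= {k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    per_metric: dict[str, list[float]] = {}
    fold_sizes = []
    for tr_idx, ho_idx in skf.split(np.zeros(len(y)), y):
        fold_sizes.append(len(ho_idx))
        res = train_eval_fn(x[tr_idx], y[tr_idx], x[ho_idx], y[ho_idx])
        for name, val in res.items():
            per_metric.setdefault(name, []).append(float(val))
    return {"fold_sizes": fold_sizes,
            "stats": {name: FoldStats.from_values(vals)
                      for name, vals in per_metric.items()}}


def ablation_grid(variants, run_fn) -> pd.DataFrame:
    """Run the requested ablation variants and tabulate their metrics.

    ``variants`` is a list of dicts with toggles
    {name, input: raw|ckpf, color: rgb|grayscale, pre_context,
    post_context, gan_augment}; ``run_fn(variant) -> dict`` executes one
    variant (typically a fixture-scale training run) and returns
    {accuracy, fold_values (optional), precision, recall, iou, f_score}.
    """
    rows = []
    for variant in variants:
        _validate_variant(variant)
        res = run_fn(variant)
        vals = np.asarray(res.get("fold_values", [res["accuracy"]]), dtype=float)
        rows.append({
            "variant": variant.get("name", _variant_name(variant)),
            "input": variant.get("input", "ckpf"),
            "color": variant.get("color", "grayscale"),
            "accuracy_pct": res["accuracy"],
            "mean_pct": float(vals.mean()),
            "variance": float(vals.var(ddof=1)) if len(vals) > 1 else 0.0,
            "sd_pct": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            "precision_pct": res.get("precision", np.nan),
            "recall_pct": res.get("recall", np.nan),
            "iou_pct": res.get("iou", np.nan),
            "f_score_pct": res.get("f_score", np.nan),
        })
    return pd.DataFrame(rows)


def _validate_variant(v: dict):
    if v.get("input", "ckpf") not in ("raw", "ckpf"):
        raise ValueError("input must be raw|ckpf")
    if v.get("color", "grayscale") not in ("rgb", "grayscale"):
        raise ValueError("color must be rgb|grayscale")
    if v.get("input") == "ckpf" and v.get("color") == "rgb":
        raise ValueError("ckpf renderings are single-channel grayscale")


def _variant_name(v: dict) -> str:
    bits = [v.get("input", "ckpf")]
    if v.get("pre_context"):
        bits.append("pre")
    if v.get("post_context"):
        bits.append("post")
    if v.get("gan_augment"):
        bits.append("gan")
    return "+".join(bits)
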