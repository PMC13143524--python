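"""Classification metrics, one-vs-one macro-AUC, fold aggregation, t-tests.

Per-class precision, recall and F1 are computed one-vs-rest from the
confusion counts and macro-averaged without class weighting; accuracy is
the trace of the confusion matrix over N.  Multi-class AUC uses the
one-vs-one strategy: for every unordered class pair (i, j) the samples of
those two classes are ranked twice — by p_i (i as positive) and by p_j
(j as positive) — the two AUCs are averaged, and the pair scores are
macro-averaged over all C(C-1)/2 pairs.  Ties count 1/2 (Mann-Whitney
convention).  Cross-fold aggregation reports mean +/- sample standard
deviation (ddof 1), and model pairs are compared with paired two-sided
t-tests on fold-wise metric differences.

Zero-denominator cells (e.g. a class never predicted) are defined as 0
and flagged rather than left undefined, so fold aggregation stays total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.metrics import roc_auc_score


def confusion_matrix(
    y_true: np.ndarray, y_pred: np.ndarray, num_classes: int
) -> np.ndarray:
    """Count matrix; entry (i, j) = # samples with true class i predicted j."""
    t = np.asarray(y_true, dtype=np.int64)
    p = np.asarray(y_pred, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    for name, v in (("true", t), ("predicted", p)):
        if v.size and (v.min() < 0 or v.max() >= num_classes):
            raise ValueError(f"{name} labels out of range [0, {num_classes})")
    m = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(m, (t, p), 1)
    return m


def normalize_confusion(counts: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Row-normalize; returns (matrix, rows flagged for zero support)."""
    counts = np.asarray(counts, dtype=np.float64)
    sums = counts.sum(axis=1, keepdims=True)
    flagged = [int(i) for i in np.flatnonzero(sums[:, 0] == 0)]
    out = np.divide(counts, np.where(sums > 0, sums, 1.0))
    return out, flagged


def macro_metrics(counts: np.ndarray) -> dict:
    """Accuracy and macro precision/recall/F1 from confusion counts.

    Per class c (one-vs-rest): TP = M[c,c], FP = column sum - TP,
    FN = row sum - TP; precision = TP/(TP+FP), recall = TP/(TP+FN),
    F1 = 2PR/(P+R); macro = unweighted mean.  Division by zero yields 0
    with the class index flagged.
    """
    m = np.asarray(counts, dtype=np.float64)
    c = m.shape[0]
    if c < 2 or m.shape[0] != m.shape[1]:
        raise ValueError("confusion matrix must be square with C >= 2")
    n = m.sum()
    tp = np.diag(m)
    fp = m.sum(axis=0) - tp
    fn = m.sum(axis=1) - tp
    flagged = []
    prec = np.zeros(c)
    rec = np.zeros(c)
    f1 = np.zeros(c)
    for i in range(c):
        if tp[i] + fp[i] > 0:
            prec[i] = tp[i] / (tp[i] + fp[i])
        else:
            flagged.append(i)
        if tp[i] + fn[i] > 0:
            rec[i] = tp[i] / (tp[i] + fn[i])
        if prec[i] + rec[i] > 0:
            f1[i] = 2 * prec[i] * rec[i] / (prec[i] + rec[i])
    return {
        "accuracy": float(tp.sum() / n) if n else 0.0,
        "macro_precision": float(prec.mean()),
        "macro_recall": float(rec.mean()),
        "macro_f1": float(f1.mean()),
        "per_class_precision": prec,
        "per_class_recall": rec,
        "per_class_f1": f1,
        "zero_division_flags": flagged,
    }


def macro_auc_ovo(
    y_true: np.ndarray, probs: np.ndarray
) -> tuple[float, list[tuple[int, int]]]:
    """One-vs-one macro-AUC; returns (auc, skipped pairs).

    A pair with samples from only one of its classes is skipped and
    flagged.  Returns NaN if every pair is skipped.
    """
    t = np.asarray(y_true, dtype=np.int64)
    p = np.asarray(probs, dtype=np.float64)
    if p.ndim != 2 or p.shape[0] != t.shape[0]:
        raise ValueError("probability matrix must be N x C aligned with labels")
    c = p.shape[1]
    pair_aucs = []
    skipped: list[tuple[int, int]] = []
    for i, j in combinations(range(c), 2):
        sel = (t == i) | (t == j)
        if not (np.any(t[sel] == i) and np.any(t[sel] == j)):
            skipped.append((i, j))
            continue
        a_ij = roc_auc_score((t[sel] == i).astype(int), p[sel, i])
        a_ji = roc_auc_score((t[sel] == j).astype(int), p[sel, j])
        pair_aucs.append(0.5 * (a_ij + a_ji))
    if not pair_aucs:
        return float("nan"), skipped
    return float(np.mean(pair_aucs)), skipped


@dataclass
class EvalReport:
    """Validation metrics of one fold (or one pooled evaluation)."""

    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    macro_auc: float
    confusion: np.ndarray  # raw counts
    confusion_normalized: np.ndarray
    per_class: pd.DataFrame
    fold: int | None = None
    flags: dict = field(default_factory=dict)

    METRICS = ("accuracy", "macro_precision", "macro_recall", "macro_f1", "macro_auc")

    def metrics(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self.METRICS}

    def to_csv(self, path: str | Path) -> None:
        rows = [{"metric": k, "value": v} for k, v in self.metrics().items()]
        pd.DataFrame(rows).to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "fold": self.fold,
            **{k: float(v) for k, v in self.metrics().items()},
            "confusion": self.confusion.tolist(),
            "confusion_normalized": self.confusion_normalized.tolist(),
            "flags": {k: list(map(str, v)) for k, v in self.flags.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def evaluate_predictions(
    y_true: np.ndarray, probs: np.ndarray, fold: int | None = None
) -> EvalReport:
    """Full fold evaluation from true labels and predicted probabilities."""
    probs = np.asarray(probs, dtype=np.float64)
    y_true = np.asarray(y_true, dtype=np.int64)
    c = probs.shape[1]
    y_pred = probs.argmax(axis=1)
    counts = confusion_matrix(y_true, y_pred, c)
    norm, zero_rows = normalize_confusion(counts)
    mm = macro_metrics(counts)
    auc, skipped = macro_auc_ovo(y_true, probs)
    top_mis = []
    for i in range(c):
        row = norm[i].copy()
        row[i] = -1
        top_mis.append(int(row.argmax()) if counts[i].sum() else -1)
    per_class = pd.DataFrame(
        {
            "class_id": np.arange(c),
            "support": counts.sum(axis=1),
            "correct_fraction": np.diag(norm),
            "precision": mm["per_class_precision"],
            "recall": mm["per_class_recall"],
            "f1": mm["per_class_f1"],
            "top_misclassified_as": top_mis,
        }
    )
    return EvalReport(
        accuracy=mm["accuracy"],
        macro_precision=mm["macro_precision"],
        macro_recall=mm["macro_recall"],
        macro_f1=mm["macro_f1"],
        macro_auc=auc,
        confusion=counts,
        confusion_normalized=norm,
        per_class=per_class,
        fold=fold,
        flags={
            "zero_support_rows": zero_rows,
            "zero_division_classes": mm["zero_division_flags"],
            "skipped_auc_pairs": skipped,
        },
    )


def roc_curves(y_true: np.ndarray, probs: np.ndarray) -> dict[int, pd.DataFrame]:
    """Per-class one-vs-rest ROC coordinate tables (fpr, tpr, threshold)."""
    from sklearn.metrics import roc_curve

    out = {}
    t = np.asarray(y_true)
    for c in range(probs.shape[1]):
        if len(np.unique(t == c)) < 2:
            continue
        fpr, tpr, thr = roc_curve((t == c).astype(int), probs[:, c])
        out[c] = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return out


# ---------------------------------------------------------------------------
# cross-fold aggregation and model comparison
# ---------------------------------------------------------------------------

def aggregate_folds(reports: list[EvalReport]) -> pd.DataFrame:
    """mean +/- sample std (ddof 1) per metric over folds.

    A single fold yields std 0 with ``flagged=True`` (std undefined).
    """
    if not reports:
        raise ValueError("no fold reports to aggregate")
    rows = []
    for metric in EvalReport.METRICS:
        vals = np.array([getattr(r, metric) for r in reports], dtype=np.float64)
        single = vals.size < 2
        rows.append(
            {
                "metric": metric,
                "mean": float(vals.mean()),
                "std": 0.0 if single else float(vals.std(ddof=1)),
                "formatted": f"{vals.mean():.4f} ± "
                f"{0.0 if single else vals.std(ddof=1):.4f}",
                "flagged": single,
            }
        )
    return pd.DataFrame(rows)


def paired_ttest(
    values_a: np.ndarray, values_b: np.ndarray, alpha: float = 0.05
) -> dict:
    """Paired two-sided t-test on fold-wise differences.

    Zero-variance differences are flagged (p undefined, reported NaN).
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length fold-paired vectors, n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        stat = 0.0 if np.allclose(d, 0.0) else np.inf * np.sign(d.mean())
        return {
            "statistic": float(stat) if np.isfinite(stat) else float(stat),
            "p_value": float("nan") if not np.allclose(d, 0.0) else 1.0,
            "significant": False,
            "zero_variance": True,
        }
    res = sstats.ttest_rel(a, b)
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "significant": bool(res.pvalue < alpha),
        "zero_variance": False,
    }


def comparison_table(
    fold_reports: dict[str, list[EvalReport]], reference: str | None = None
) -> pd.DataFrame:
    """Mean +/- std table over variants with significance asterisks.

    Each non-reference variant is compared to ``reference`` (default: the
    first variant) metric-by-metric with a paired t-test; significant
    differences (p < 0.05) are marked with '*' on the formatted value.
    """
    names = list(fold_reports.keys())
    if reference is None:
        reference = names[0]
    ref_vals = {
        m: np.array([getattr(r, m) for r in fold_reports[reference]])
        for m in EvalReport.METRICS
    }
    rows = []
    for name in names:
        row: dict = {"model": name}
        for m in EvalReport.METRICS:
            vals = np.array([getattr(r, m) for r in fold_reports[name]])
            mean = vals.mean()
            std = vals.std(ddof=1) if vals.size > 1 else 0.0
            star = ""
            if name != reference and vals.size > 1:
                tt = paired_ttest(vals, ref_vals[m])
                if tt["significant"]:
                    star = "*"
            row[m] = f"{mean:.4f} ± {std:.4f}{star}"
        rows.append(row)
    return pd.DataFrame(rows)
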