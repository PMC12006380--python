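"""Performance metrics for attention prediction.

Point-wise accuracy/precision/recall/F1 and Cohen's kappa on the 2 Hz
grid (masked points excluded pairwise), the two-sample KS test comparing
predicted and reference SA duration distributions, the analytic null
baselines (all-negative / all-positive predictions), and interval-level
inter-rater agreement over the elementary-period partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .screening import AttentionIntervals

__all__ = [
    "pointwise_metrics",
    "cohens_kappa",
    "ks_durations",
    "null_baselines",
    "interval_agreement",
    "EvalReport",
    "evaluate_sessions",
]


def _paired(pred, truth) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape:
        raise ValueError("prediction and truth must have equal length")
    keep = np.isfinite(p) & np.isfinite(t)
    if not keep.any():
        raise ValueError("no overlapping unmasked points")
    return p[keep].astype(int), t[keep].astype(int)


def confusion_counts(pred, truth) -> dict[str, int]:
    p, t = _paired(pred, truth)
    return {
        "TP": int(np.sum((p == 1) & (t == 1))),
        "FP": int(np.sum((p == 1) & (t == 0))),
        "FN": int(np.sum((p == 0) & (t == 1))),
        "TN": int(np.sum((p == 0) & (t == 0))),
    }


def pointwise_metrics(pred, truth) -> dict[str, float]:
    """Accuracy, precision, recall and F1 from the 2x2 confusion counts.

    Undefined ratios (empty denominators) are reported as NaN, and F1 is
    NaN whenever precision or recall is.
    """
    c = confusion_counts(pred, truth)
    tp, fp, fn, tn = c["TP"], c["FP"], c["FN"], c["TN"]
    total = tp + fp + fn + tn
    acc = (tp + tn) / total
    prec = tp / (tp + fp) if tp + fp > 0 else np.nan
    rec = tp / (tp + fn) if tp + fn > 0 else np.nan
    if np.isnan(prec) or np.isnan(rec) or prec + rec == 0:
        f1 = np.nan if np.isnan(prec) or np.isnan(rec) else 0.0
    else:
        f1 = 2 * prec * rec / (prec + rec)
    return {"accuracy": acc, "precision": prec, "recall": rec, "f1": f1, **c}


def cohens_kappa(pred, truth) -> float:
    """kappa = (p_o - p_e) / (1 - p_e) with marginal-product chance agreement."""
    p, t = _paired(pred, truth)
    n = p.size
    po = np.mean(p == t)
    pe = (np.mean(p == 1) * np.mean(t == 1)) + (np.mean(p == 0) * np.mean(t == 0))
    if 1.0 - pe == 0:
        return np.nan
    return float((po - pe) / (1.0 - pe))


def ks_durations(a: AttentionIntervals | np.ndarray, b: AttentionIntervals | np.ndarray) -> tuple[float, float]:
    """Two-sample KS test on pooled interval durations.

    The p-value is exact for small samples and asymptotic for large ones
    (the convention of standard statistical software).
    """
    da = a.durations if isinstance(a, AttentionIntervals) else np.asarray(a, dtype=float)
    db = b.durations if isinstance(b, AttentionIntervals) else np.asarray(b, dtype=float)
    if da.size == 0 or db.size == 0:
        raise ValueError("both duration samples must be non-empty")
    res = stats.ks_2samp(da, db)
    return float(res.statistic), float(res.pvalue)


def null_baselines(truth) -> dict[str, float]:
    """Analytic baselines: all-negative accuracy and all-positive P/R/F1."""
    t = np.asarray(truth, dtype=float)
    t = t[np.isfinite(t)].astype(int)
    prevalence = float(np.mean(t == 1))
    f1_pos = 2 * prevalence / (prevalence + 1.0) if prevalence > 0 else 0.0
    return {
        "prevalence": prevalence,
        "all_negative_accuracy": 1.0 - prevalence,
        "all_positive_precision": prevalence,
        "all_positive_recall": 1.0 if prevalence > 0 else np.nan,
        "all_positive_f1": f1_pos,
    }


def interval_agreement(
    a: AttentionIntervals,
    b: AttentionIntervals,
    session_span: tuple[float, float],
) -> float:
    """Cohen's kappa over matched attention/inattention periods.

    Each coder's session is an alternating sequence of attention and
    inattention periods.  Every period of either coder contributes one
    equally weighted tally: it agrees when the other coder has an
    overlapping period of the same class (any degree of overlap), and
    otherwise is labelled with the other coder's class occupying the
    largest share of it.  Kappa is computed on the pooled 2x2 table.
    """
    t0, t1 = session_span
    if t1 <= t0:
        raise ValueError("session span must have positive length")

    def periods(iv: AttentionIntervals) -> list[tuple[float, float, int]]:
        out: list[tuple[float, float, int]] = []
        cursor = t0
        for on, off in iv:
            on, off = max(on, t0), min(off, t1)
            if on > cursor:
                out.append((cursor, on, 0))
            if off > on:
                out.append((on, off, 1))
            cursor = max(cursor, off)
        if cursor < t1:
            out.append((cursor, t1, 0))
        return out

    per_a, per_b = periods(a), periods(b)

    def other_label(p0: float, p1: float, label: int, others) -> int:
        share = {0: 0.0, 1: 0.0}
        for q0, q1, lab in others:
            share[lab] += max(0.0, min(p1, q1) - max(p0, q0))
        if share[label] > 0:
            return label  # any overlap with the same class counts as agreement
        return int(share[1] > share[0])

    tallies_a, tallies_b = [], []
    for p0, p1, lab in per_a:
        tallies_a.append(lab)
        tallies_b.append(other_label(p0, p1, lab, per_b))
    for q0, q1, lab in per_b:
        tallies_b.append(lab)
        tallies_a.append(other_label(q0, q1, lab, per_a))
    return cohens_kappa(np.array(tallies_a), np.array(tallies_b))


@dataclass
class EvalReport:
    """Per-session and pooled metrics for one prediction source."""

    per_session: list[dict[str, float]] = field(default_factory=list)
    pooled_mean: dict[str, float] = field(default_factory=dict)
    pooled_sd: dict[str, float] = field(default_factory=dict)
    ks_statistic: float = np.nan
    ks_p: float = np.nan
    nulls: dict[str, float] = field(default_factory=dict)


def evaluate_sessions(
    preds: list[np.ndarray],
    truths: list[np.ndarray],
    pred_intervals: list[AttentionIntervals] | None = None,
    truth_intervals: list[AttentionIntervals] | None = None,
) -> EvalReport:
    """Aggregate point-wise metrics (mean +/- sd across sessions) and the
    pooled duration KS test."""
    report = EvalReport()
    for p, t in zip(preds, truths):
        m = pointwise_metrics(p, t)
        m["kappa"] = cohens_kappa(p, t)
        report.per_session.append(m)
    keys = ("accuracy", "precision", "recall", "f1", "kappa")
    for k in keys:
        vals = np.array([m[k] for m in report.per_session], dtype=float)
        report.pooled_mean[k] = float(np.nanmean(vals))
        report.pooled_sd[k] = float(np.nanstd(vals, ddof=1)) if vals.size > 1 else 0.0
    pooled_truth = np.concatenate([np.asarray(t, float) for t in truths])
    report.nulls = null_baselines(pooled_truth)
    if pred_intervals is not None and truth_intervals is not None:
        da = np.concatenate([iv.durations for iv in pred_intervals]) if pred_intervals else np.empty(0)
        db = np.concatenate([iv.durations for iv in truth_intervals]) if truth_intervals else np.empty(0)
        if da.size and db.size:
            report.ks_statistic, report.ks_p = ks_durations(da, db)
    return report
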