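"""Classifier evaluation: ROC and PR curves, their AUCs, Cohen's kappa and
confusion matrices.

The threshold sweep walks the distinct scores in descending order, moving
all tied scores across the threshold together.  ROC AUC is the trapezoid
area, which on tie-grouped points equals the Mann-Whitney U statistic
normalized by n_pos * n_neg.  PR AUC is the rectangle-under-step sum
sum_i (R_i - R_{i-1}) * P_i with each recall segment taking the precision of
its higher-recall endpoint (average-precision convention); a trapezoid
variant is available behind a flag for comparison with tools that
interpolate PR linearly.  The PR point at recall 0 is assigned the precision
of the highest-score threshold rather than interpolating through the
undefined 0/0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np


@dataclass
class EvaluationReport:
    """Curves and summary statistics for one scored, labeled set."""

    roc_points: list[tuple[float, float]]          # (FPR, TPR)
    pr_points: list[tuple[float, float]]           # (recall, precision)
    roc_auc: float
    pr_auc: float
    pr_auc_trapezoid: float
    kappa: float
    confusion: tuple[tuple[int, int], tuple[int, int]]  # [[TP, FN], [FP, TN]]
    threshold_table: list[tuple[float, int, int, int, int]]  # (thr, TP, FP, TN, FN)
    n: int = 0

    @property
    def accuracy(self) -> float:
        (tp, fn), (fp, tn) = self.confusion
        return (tp + tn) / max(1, tp + fn + fp + tn)

    @property
    def precision(self) -> float:
        (tp, _), (fp, _) = self.confusion
        return tp / max(1, tp + fp)

    @property
    def recall(self) -> float:
        (tp, fn), _ = self.confusion
        return tp / max(1, tp + fn)


def roc_pr_curves(scores: Sequence[float], labels: Sequence[int],
                  decision_threshold: float = 0.5) -> EvaluationReport:
    """Sweep thresholds over the scores and assemble an
    :class:`EvaluationReport`.

    ``labels`` are 1 for the positive (TP) class, 0 otherwise; ``scores``
    are classifier scores where larger means more positive.  The confusion
    matrix and kappa are evaluated at ``decision_threshold`` with "positive
    iff score > threshold" (matching the forest's tie-to-FP rule).
    Raises ``ValueError`` when only one class is present.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to draw curves")

    order = np.argsort(-s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    # group ties: indices where a threshold block ends
    distinct = np.flatnonzero(np.diff(s_sorted) != 0)
    block_ends = np.append(distinct, len(s_sorted) - 1)

    cum_tp = np.cumsum(y_sorted)[block_ends]
    cum_fp = (block_ends + 1) - cum_tp
    thresholds = s_sorted[block_ends]

    tpr = cum_tp / n_pos
    fpr = cum_fp / n_neg
    precision = cum_tp / (cum_tp + cum_fp)
    recall = tpr

    roc_points = [(0.0, 0.0)] + list(zip(fpr.tolist(), tpr.tolist()))
    roc_auc = float(np.trapezoid(np.concatenate([[0.0], tpr]),
                                 np.concatenate([[0.0], fpr])))

    pr_points = [(0.0, float(precision[0]))] + list(
        zip(recall.tolist(), precision.tolist()))
    d_recall = np.diff(np.concatenate([[0.0], recall]))
    pr_auc = float((d_recall * precision).sum())
    prev_prec = np.concatenate([[precision[0]], precision[:-1]])
    pr_auc_trap = float((d_recall * (precision + prev_prec) / 2.0).sum())

    threshold_table = [
        (float(thresholds[i]), int(cum_tp[i]), int(cum_fp[i]),
         int(n_neg - cum_fp[i]), int(n_pos - cum_tp[i]))
        for i in range(len(thresholds))
    ]

    pred = (s > decision_threshold).astype(np.int64)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    confusion = ((tp, fn), (fp, tn))

    return EvaluationReport(roc_points=roc_points, pr_points=pr_points,
                            roc_auc=roc_auc, pr_auc=pr_auc,
                            pr_auc_trapezoid=pr_auc_trap,
                            kappa=cohen_kappa(confusion), confusion=confusion,
                            threshold_table=threshold_table, n=len(y))


def cohen_kappa(confusion: Sequence[Sequence[int]]) -> float:
    """Chance-corrected agreement from a 2x2 confusion matrix.

    kappa = (p_o - p_e) / (1 - p_e), with p_o the observed agreement and
    p_e the chance agreement from the marginals; defined as 0 when p_e = 1
    (degenerate one-cell tables).
    """
    (a, b), (c, d) = confusion
    if min(a, b, c, d) < 0:
        raise ValueError("confusion counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = (a + d) / n
    # marginals: predicted-positive = a + c, actual-positive = a + b
    p_e = ((a + b) * (a + c) + (c + d) * (b + d)) / (n * n)
    if p_e == 1.0:
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def write_curves(report: EvaluationReport, out_dir) -> dict[str, Path]:
    """Write curve TSVs, a metrics JSON and a rendered plot under
    ``out_dir``; byte-deterministic for a given report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "roc": out / "roc_curve.tsv",
        "pr": out / "pr_curve.tsv",
        "thresholds": out / "threshold_table.tsv",
        "metrics": out / "metrics.json",
        "plot": out / "curves.png",
    }
    with open(paths["roc"], "w") as fh:
        fh.write("fpr\ttpr\n")
        for x, yv in report.roc_points:
            fh.write(f"{x:.10g}\t{yv:.10g}\n")
    with open(paths["pr"], "w") as fh:
        fh.write("recall\tprecision\n")
        for x, yv in report.pr_points:
            fh.write(f"{x:.10g}\t{yv:.10g}\n")
    with open(paths["thresholds"], "w") as fh:
        fh.write("threshold\ttp\tfp\ttn\tfn\n")
        for thr, tp, fp, tn, fn in report.threshold_table:
            fh.write(f"{thr:.10g}\t{tp}\t{fp}\t{tn}\t{fn}\n")
    metrics = {
        "roc_auc": report.roc_auc,
        "pr_auc": report.pr_auc,
        "pr_auc_trapezoid": report.pr_auc_trapezoid,
        "kappa": report.kappa,
        "accuracy": report.accuracy,
        "precision": report.precision,
        "recall": report.recall,
        "n": report.n,
        "confusion": [list(r) for r in report.confusion],
    }
    with open(paths["metrics"], "w") as fh:
        json.dump(metrics, fh, sort_keys=True, indent=2)
        fh.write("\n")
    _plot_curves(report, paths["plot"])
    return paths


def _plot_curves(report: EvaluationReport, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.plot(*zip(*report.roc_points), lw=1.5)
    ax1.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax1.set_xlabel("FPR")
    ax1.set_ylabel("TPR")
    ax1.set_title(f"ROC (AUC = {report.roc_auc:.4f})")
    ax2.plot(*zip(*report.pr_points), lw=1.5)
    ax2.set_xlabel("Recall")
    ax2.set_ylabel("Precision")
    ax2.set_ylim(-0.02, 1.02)
    ax2.set_title(f"PR (AUC = {report.pr_auc:.4f})")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
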