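"""Binary-classification evaluation: confusion matrix, threshold
scores, ROC/AUC, and training-curve plots.

All metrics are computed directly from counts:

    accuracy  = (TP + TN) / n
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 · precision · recall / (precision + recall)

(F1 is the harmonic mean of precision and recall, the standard
definition.) The ROC curve sweeps the decision threshold over the
unique predicted probabilities, grouping ties into single steps, and
AUC is the trapezoidal area — equivalently the Mann–Whitney
probability that a random positive scores above a random negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["MetricsReport", "confusion", "scores", "roc_auc", "evaluate_predictions",
           "curve_log_to_plot"]


@dataclass
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    threshold: float = 0.5
    auc: float | None = None
    roc_points: list = field(default_factory=list)
    degenerate: dict = field(default_factory=dict)  # zero-denominator flags

    def to_dict(self) -> dict:
        return asdict(self)


def confusion(labels, probabilities, threshold: float = 0.5) -> dict:
    """Exact confusion counts; prediction = probability >= threshold."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must have equal length")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary")
    pred = (p >= threshold).astype(int)
    return {
        "tp": int(np.sum((pred == 1) & (y == 1))),
        "fp": int(np.sum((pred == 1) & (y == 0))),
        "tn": int(np.sum((pred == 0) & (y == 0))),
        "fn": int(np.sum((pred == 0) & (y == 1))),
    }


def scores(counts: dict) -> dict:
    """Accuracy/precision/recall/F1 from confusion counts.

    Zero-denominator cases return 0.0 and set a flag under
    ``"degenerate"`` rather than raising.
    """
    tp, fp, tn, fn = counts["tp"], counts["fp"], counts["tn"], counts["fn"]
    n = tp + fp + tn + fn
    if n < 1:
        raise ValueError("empty confusion matrix")
    degenerate = {}
    accuracy = (tp + tn) / n
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision, degenerate["precision"] = 0.0, True
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        recall, degenerate["recall"] = 0.0, True
    if precision + recall > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
    else:
        f1, degenerate["f1"] = 0.0, True
    return {"accuracy": accuracy, "precision": precision, "recall": recall,
            "f1": f1, "degenerate": degenerate}


def roc_auc(labels, probabilities) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) and trapezoidal AUC.

    Thresholds sweep the unique probabilities in decreasing order;
    equal probabilities collapse into one step. Requires both classes.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")

    order = np.argsort(-p, kind="stable")
    p_sorted, y_sorted = p[order], y[order]
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    # keep the last index of each tie group
    distinct = np.r_[np.diff(p_sorted) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def evaluate_predictions(labels, probabilities, threshold: float = 0.5) -> MetricsReport:
    """Full report: confusion, threshold scores, ROC and AUC."""
    counts = confusion(labels, probabilities, threshold)
    sc = scores(counts)
    y = np.asarray(labels, dtype=int)
    roc_points: list = []
    auc = None
    if 0 < y.sum() < y.size:
        roc_points, auc = roc_auc(labels, probabilities)
    return MetricsReport(
        tp=counts["tp"], fp=counts["fp"], tn=counts["tn"], fn=counts["fn"],
        accuracy=sc["accuracy"], precision=sc["precision"], recall=sc["recall"],
        f1=sc["f1"], threshold=threshold, auc=auc, roc_points=roc_points,
        degenerate=sc["degenerate"],
    )


def curve_log_to_plot(round_logs, out_dir, fmt: str = "png") -> list[str]:
    """Per-client + global training/validation accuracy and loss panels.

    ``round_logs`` is the list produced by the federated orchestrator.
    Saves one figure per metric family and returns the file paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    if not round_logs:
        raise ValueError("no rounds to plot")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    n_clients = len(round_logs[0].client_metrics)
    rounds = [rl.round_index for rl in round_logs]
    files = []
    for metric, ylabel in (("accuracy", "accuracy"), ("loss", "loss")):
        fig, axes = plt.subplots(
            1, n_clients + 1, figsize=(4 * (n_clients + 1), 3.2), squeeze=False
        )
        for k in range(n_clients):
            ax = axes[0][k]
            ax.plot(rounds, [rl.client_metrics[k][f"train_{metric}"] for rl in round_logs],
                    label="train")
            ax.plot(rounds, [rl.client_metrics[k][f"val_{metric}"] for rl in round_logs],
                    label="validation")
            ax.set_title(f"Client {k + 1}")
            ax.set_xlabel("round")
            ax.set_ylabel(ylabel)
            ax.legend()
        ax = axes[0][n_clients]
        ax.plot(rounds, [rl.global_metrics[f"val_{metric}"] for rl in round_logs],
                label="validation", color="C1")
        ax.set_title("Global model")
        ax.set_xlabel("round")
        ax.set_ylabel(ylabel)
        ax.legend()
        fig.tight_layout()
        fname = out_dir / f"{metric}_curves.{fmt}"
        fig.savefig(fname)
        plt.close(fig)
        files.append(str(fname))
    return files
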