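"""Binary-classifier evaluation: confusion counts, six metrics, ROC/AUC.

Coral is the positive class throughout. Metrics with an undefined
denominator (e.g. precision with no positive predictions) are reported as
``None`` rather than silently zeroed, so comparisons across runs stay
honest.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

REPORT_DECIMALS = 4


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with coral as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """The six evaluation measures; None marks an undefined denominator."""

    precision: float | None
    recall: float | None
    specificity: float | None
    accuracy: float
    f_measure: float | None
    kappa: float | None
    n: int

    def rounded(self) -> dict:
        """Presentation form: 4-decimal rounding, None -> "undefined"."""
        out = {}
        for k, v in asdict(self).items():
            if v is None:
                out[k] = "undefined"
            elif k == "n":
                out[k] = v
            else:
                out[k] = round(v, REPORT_DECIMALS)
        return out


@dataclass(frozen=True)
class ROCCurve:
    """ROC points ordered by false-positive rate, with trapezoidal AUC."""

    fpr: tuple[float, ...]
    tpr: tuple[float, ...]
    auc: float


def confusion(pred: np.ndarray, true: np.ndarray) -> ConfusionMatrix:
    """Tabulate binary predictions against truth (True/1 = coral)."""
    pred = np.asarray(pred).astype(bool)
    true = np.asarray(true).astype(bool)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {true.shape}")
    return ConfusionMatrix(
        tp=int(np.sum(pred & true)),
        fn=int(np.sum(~pred & true)),
        fp=int(np.sum(pred & ~true)),
        tn=int(np.sum(~pred & ~true)),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Precision, recall, specificity, accuracy, F-measure and kappa.

    Kappa is chance-corrected accuracy, with expected agreement computed
    from the row/column marginals; with balanced truth classes it reduces
    to ``2 * accuracy - 1``.
    """
    n = cm.n
    if n == 0:
        raise ValueError("empty confusion matrix")
    precision = _ratio(cm.tp, cm.tp + cm.fp)
    recall = _ratio(cm.tp, cm.tp + cm.fn)
    specificity = _ratio(cm.tn, cm.tn + cm.fp)
    accuracy = (cm.tp + cm.tn) / n
    if precision is None or recall is None or precision + recall == 0:
        f_measure = None
    else:
        f_measure = 2 * precision * recall / (precision + recall)
    p0 = accuracy
    pe = ((cm.tp + cm.fn) * (cm.tp + cm.fp) + (cm.tn + cm.fp) * (cm.tn + cm.fn)) / (n * n)
    kappa = None if pe == 1 else (p0 - pe) / (1 - pe)
    return MetricsReport(
        precision=precision,
        recall=recall,
        specificity=specificity,
        accuracy=accuracy,
        f_measure=f_measure,
        kappa=kappa,
        n=n,
    )


def roc_and_auc(probabilities: np.ndarray, true: np.ndarray) -> ROCCurve:
    """ROC by sweeping thresholds over the unique scores; trapezoidal AUC."""
    prob = np.asarray(probabilities, dtype=float)
    true = np.asarray(true).astype(bool)
    if prob.shape != true.shape:
        raise ValueError("probabilities and labels differ in length")
    if np.any((prob < 0) | (prob > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    n_pos = int(true.sum())
    n_neg = int((~true).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes in the truth labels")
    order = np.argsort(-prob, kind="stable")
    sorted_true = true[order]
    sorted_prob = prob[order]
    tps = np.cumsum(sorted_true)
    fps = np.cumsum(~sorted_true)
    # keep one operating point per distinct threshold
    distinct = np.r_[np.nonzero(np.diff(sorted_prob))[0], len(sorted_prob) - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=tuple(fpr.tolist()), tpr=tuple(tpr.tolist()), auc=auc)


def plot_roc(roc: ROCCurve, path: str | Path, label: str = "classifier") -> Path:
    """Save a ROC plot with the chance diagonal for reference."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(roc.fpr, roc.tpr, label=f"{label} (AUC = {roc.auc:.4f})")
    ax.plot([0, 1], [0, 1], "k--", linewidth=0.8, label="chance")
    ax.set_xlabel("false positive rate (1 - specificity)")
    ax.set_ylabel("true positive rate (recall)")
    ax.legend(loc="lower right")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def evaluate(pred: np.ndarray, true: np.ndarray) -> tuple[ConfusionMatrix, MetricsReport]:
    cm = confusion(pred, true)
    return cm, metrics(cm)


def write_report(
    path: str | Path,
    report: MetricsReport,
    cm: ConfusionMatrix | None = None,
    roc: ROCCurve | None = None,
    extra: dict | None = None,
) -> Path:
    payload: dict = {"metrics": report.rounded()}
    if cm is not None:
        payload["confusion"] = asdict(cm)
    if roc is not None:
        payload["roc"] = {"fpr": roc.fpr, "tpr": roc.tpr, "auc": round(roc.auc, REPORT_DECIMALS)}
    if extra:
        payload.update(extra)
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2))
    return path
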