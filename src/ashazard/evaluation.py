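"""Cross-validation statistics, ROC/AUC, and probability-cutoff selection.

All statistics are computed from first principles on a 2x2 confusion matrix
with exceedance (label 1) as the positive class.  Cutoff selection scans a
fixed grid of probabilities and returns the grid point where two diagnostic
curves (sensitivity/specificity, or PPV/NPV) come closest — the operating
point at which the classifier treats low and high concentrations equally
well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest, rankdata

__all__ = [
    "ConfusionMatrix2x2",
    "ConfusionStats",
    "CutoffResult",
    "confusion_stats",
    "roc_auc",
    "find_cutoff",
]


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    """Counts ``n_<pred><ref>``: prediction index first, reference second."""

    n00: int
    n01: int
    n10: int
    n11: int

    def __post_init__(self) -> None:
        counts = (self.n00, self.n01, self.n10, self.n11)
        if any(c < 0 for c in counts):
            raise ValueError("confusion counts must be >= 0")
        if sum(counts) < 1:
            raise ValueError("confusion matrix must contain at least one observation")

    @classmethod
    def from_labels(cls, predicted, reference) -> "ConfusionMatrix2x2":
        pred = np.asarray(predicted, dtype=np.int64)
        ref = np.asarray(reference, dtype=np.int64)
        if pred.shape != ref.shape:
            raise ValueError("predicted and reference must have equal length")
        if not (np.isin(pred, (0, 1)).all() and np.isin(ref, (0, 1)).all()):
            raise ValueError("labels must be binary 0/1")
        return cls(
            n00=int(((pred == 0) & (ref == 0)).sum()),
            n01=int(((pred == 0) & (ref == 1)).sum()),
            n10=int(((pred == 1) & (ref == 0)).sum()),
            n11=int(((pred == 1) & (ref == 1)).sum()),
        )

    @property
    def total(self) -> int:
        return self.n00 + self.n01 + self.n10 + self.n11


@dataclass(frozen=True)
class ConfusionStats:
    """The full statistic set for a 2x2 matrix, positive class = exceedance.

    Statistics whose denominator is empty are reported as ``None`` rather
    than NaN.  ``p_value_acc_gt_nir`` is the one-sided exact binomial
    probability of observing at least the achieved number of correct
    classifications if the true accuracy were the no-information rate.
    """

    accuracy: float
    no_information_rate: float
    p_value_acc_gt_nir: float
    kappa: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    prevalence: float
    balanced_accuracy: float | None

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "no_information_rate": self.no_information_rate,
            "p_value_acc_gt_nir": self.p_value_acc_gt_nir,
            "kappa": self.kappa,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "prevalence": self.prevalence,
            "balanced_accuracy": self.balanced_accuracy,
        }


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def confusion_stats(matrix: ConfusionMatrix2x2) -> ConfusionStats:
    """All confusion-matrix statistics, exceedance (1) as positive class.

    sensitivity = n11 / (reference-1 marginal); specificity = n00 /
    (reference-0 marginal); PPV/NPV use the prediction marginals; the
    no-information rate is the larger reference-class share; Cohen's kappa
    uses expected agreement from the row x column marginals.
    """
    m = matrix
    n = m.total
    correct = m.n00 + m.n11
    accuracy = correct / n

    ref0 = m.n00 + m.n10
    ref1 = m.n01 + m.n11
    pred0 = m.n00 + m.n01
    pred1 = m.n10 + m.n11

    nir = max(ref0, ref1) / n
    p_value = binomtest(correct, n, nir, alternative="greater").pvalue

    pe = (pred0 / n) * (ref0 / n) + (pred1 / n) * (ref1 / n)
    kappa = (accuracy - pe) / (1.0 - pe) if pe < 1.0 else None

    sensitivity = _ratio(m.n11, ref1)
    specificity = _ratio(m.n00, ref0)
    ppv = _ratio(m.n11, pred1)
    npv = _ratio(m.n00, pred0)
    prevalence = ref1 / n
    balanced = (
        (sensitivity + specificity) / 2.0
        if sensitivity is not None and specificity is not None
        else None
    )
    return ConfusionStats(
        accuracy=accuracy,
        no_information_rate=nir,
        p_value_acc_gt_nir=p_value,
        kappa=kappa,
        sensitivity=sensitivity,
        specificity=specificity,
        ppv=ppv,
        npv=npv,
        prevalence=prevalence,
        balanced_accuracy=balanced,
    )


def render_confusion_report(matrix: ConfusionMatrix2x2, stats: ConfusionStats) -> str:
    """Plain-text rendering of the matrix and statistics table."""
    def fmt(v):
        return "undefined" if v is None else f"{v:.4f}"

    lines = [
        "            Reference",
        "Prediction      0      1",
        f"         0  {matrix.n00:5d}  {matrix.n01:5d}",
        f"         1  {matrix.n10:5d}  {matrix.n11:5d}",
        "",
        f"Accuracy (Acc)            {fmt(stats.accuracy)}",
        f"No information rate (NIR) {fmt(stats.no_information_rate)}",
        f"p value (Acc > NIR)       {stats.p_value_acc_gt_nir:.3g}",
        f"Cohen's kappa             {fmt(stats.kappa)}",
        f"Sensitivity               {fmt(stats.sensitivity)}",
        f"Specificity               {fmt(stats.specificity)}",
        f"Positive predictive value {fmt(stats.ppv)}",
        f"Negative predictive value {fmt(stats.npv)}",
        f"Prevalence                {fmt(stats.prevalence)}",
        f"Balanced accuracy         {fmt(stats.balanced_accuracy)}",
    ]
    return "\n".join(lines)


def roc_auc(probabilities, labels) -> float:
    """Area under the ROC curve as pairwise concordance.

    AUC = P(score of a random positive > score of a random negative), with
    ties counted 1/2 — computed via the rank-sum identity, equivalent to
    trapezoidal integration of the ROC curve.
    """
    scores = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=np.int64)
    if scores.shape != y.shape:
        raise ValueError("probabilities and labels must have equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(scores)  # average ranks give ties 1/2 credit
    pos_rank_sum = ranks[y == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class CutoffResult:
    """Selected probability cutoff and the full diagnostic curves."""

    cutoff: float
    criterion: str
    accuracy_at_cutoff: float
    curves: pd.DataFrame  # columns: probability, sensitivity, specificity, ppv, npv, accuracy


_CRITERIA = {
    "sens_spec": ("sensitivity", "specificity"),
    "ppv_npv": ("ppv", "npv"),
}


def cutoff_curves(probabilities, labels, grid_size: int = 100) -> pd.DataFrame:
    """Sensitivity, specificity, PPV, NPV and accuracy over a probability grid.

    The grid is ``grid_size`` evenly spaced probabilities spanning [0, 1]
    inclusive.  At each grid probability c the classification rule is
    ``predict 1 iff probability > c``.  Undefined statistics (empty
    denominator) are NaN in the returned frame.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=np.int64)
    if not ((y == 0) | (y == 1)).all():
        raise ValueError("labels must be binary 0/1")
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("cutoff analysis requires both classes present")

    grid = np.linspace(0.0, 1.0, grid_size)
    rows = []
    for c in grid:
        pred = (p > c).astype(np.int64)
        m = ConfusionMatrix2x2.from_labels(pred, y)
        ref1 = m.n01 + m.n11
        ref0 = m.n00 + m.n10
        pred1 = m.n10 + m.n11
        pred0 = m.n00 + m.n01
        rows.append(
            {
                "probability": c,
                "sensitivity": m.n11 / ref1 if ref1 else np.nan,
                "specificity": m.n00 / ref0 if ref0 else np.nan,
                "ppv": m.n11 / pred1 if pred1 else np.nan,
                "npv": m.n00 / pred0 if pred0 else np.nan,
                "accuracy": (m.n00 + m.n11) / m.total,
            }
        )
    return pd.DataFrame(rows)


def find_cutoff(
    probabilities,
    labels,
    criterion: str = "sens_spec",
    grid_size: int = 100,
) -> CutoffResult:
    """Probability cutoff where the two curves of ``criterion`` intersect.

    Scans the inclusive [0, 1] grid, computes both curves, and returns the
    grid probability minimizing |curveA - curveB|.  Selection is restricted
    to interior grid points (the endpoints classify everything into one
    class and are degenerate); among ties the lowest probability wins.
    """
    if criterion not in _CRITERIA:
        raise ValueError(f"criterion must be one of {sorted(_CRITERIA)}, got {criterion!r}")
    curves = cutoff_curves(probabilities, labels, grid_size)
    a_name, b_name = _CRITERIA[criterion]
    interior = curves.iloc[1:-1]
    diff = (interior[a_name] - interior[b_name]).abs()
    valid = diff.dropna()
    if valid.empty:
        raise ValueError(
            f"curves {a_name}/{b_name} are undefined over the whole interior grid"
        )
    best = valid.idxmin()  # idxmin returns the first (lowest-probability) minimizer
    cutoff = float(curves.loc[best, "probability"])
    return CutoffResult(
        cutoff=cutoff,
        criterion=criterion,
        accuracy_at_cutoff=float(curves.loc[best, "accuracy"]),
        curves=curves,
    )
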