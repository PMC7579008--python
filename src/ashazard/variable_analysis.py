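"""Variable importance and binned predictor-exceedance correlation.

Two complementary diagnostics of how predictors relate to exceedance:

* **Permutation importance** — the drop in classification accuracy when one
  predictor's values are shuffled (all one-hot columns of a categorical are
  shuffled together, preserving its within-variable structure), plus the
  forest's mean decrease in Gini impurity; both can be max-normalized for
  display.

* **Binned correlation** — predictor values are sorted into equal-count
  bins (bin count from Sturges' rule by default), the exceedance proportion
  per bin is computed, and the rank correlation (Kendall tau-b) between bin
  means and proportions summarizes the direction of the relationship.
  Pearson's r over the same bin summaries is also reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .forest import FittedForest, predict_class_table
from .prep import ModelingTable

__all__ = [
    "sturges_bins",
    "BinnedCorrelation",
    "binned_exceedance_correlation",
    "permutation_importance",
    "gini_importance",
    "importance_table",
    "normalize_importance",
]


def sturges_bins(n: int) -> int:
    """Sturges' rule for the number of bins: ceil(1 + log2 n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return math.ceil(1.0 + math.log2(n))


@dataclass
class BinnedCorrelation:
    """Equal-count-bin summary of one predictor against exceedance."""

    n_bins: int
    bin_means: np.ndarray
    bin_proportions: np.ndarray
    bin_counts: np.ndarray
    tau_b: float | None
    p_value: float | None
    significant: bool
    pearson_r: float | None
    pearson_p: float | None
    defined: bool


def binned_exceedance_correlation(
    values, labels, n_bins: int | None = None
) -> BinnedCorrelation:
    """Correlate binned predictor means with per-bin exceedance proportions.

    Values are stably sorted and split into ``n_bins`` equal-count bins
    (any remainder spread over the first bins; ties may straddle bin
    boundaries).  Kendall tau-b with its two-sided p-value is the headline
    statistic; significance is declared at p < 0.05.  A predictor with a
    single distinct value has no defined correlation and is flagged with
    ``defined=False`` instead of silently reporting 0.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=np.int64)
    if x.shape != y.shape:
        raise ValueError("values and labels must have equal length")
    if n_bins is None:
        n_bins = sturges_bins(x.size)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if x.size < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} observations, got {x.size}")

    order = np.argsort(x, kind="stable")
    chunks = np.array_split(order, n_bins)  # first (n % n_bins) chunks get the extra row
    bin_means = np.array([x[c].mean() for c in chunks])
    bin_props = np.array([y[c].mean() for c in chunks])
    bin_counts = np.array([c.size for c in chunks])

    if np.unique(x).size < 2:
        return BinnedCorrelation(
            n_bins=n_bins,
            bin_means=bin_means,
            bin_proportions=bin_props,
            bin_counts=bin_counts,
            tau_b=None,
            p_value=None,
            significant=False,
            pearson_r=None,
            pearson_p=None,
            defined=False,
        )

    tau = stats.kendalltau(bin_means, bin_props)  # tau-b: tie-corrected
    if np.unique(bin_means).size > 1 and np.unique(bin_props).size > 1:
        pear = stats.pearsonr(bin_means, bin_props)
        pearson_r, pearson_p = float(pear.statistic), float(pear.pvalue)
    else:
        pearson_r = pearson_p = None
    tau_defined = not np.isnan(tau.statistic)
    return BinnedCorrelation(
        n_bins=n_bins,
        bin_means=bin_means,
        bin_proportions=bin_props,
        bin_counts=bin_counts,
        tau_b=float(tau.statistic) if tau_defined else None,
        p_value=float(tau.pvalue) if tau_defined else None,
        significant=bool(tau_defined and tau.pvalue < 0.05),
        pearson_r=pearson_r,
        pearson_p=pearson_p,
        defined=tau_defined,
    )


def _accuracy(model: FittedForest, frame: pd.DataFrame, labels: np.ndarray) -> float:
    return float((predict_class_table(model, frame) == labels).mean())


def permutation_importance(
    model: FittedForest,
    data: ModelingTable,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.Series:
    """Mean decrease in accuracy when each raw predictor is shuffled.

    For each predictor the column is shuffled ``n_repeats`` times (one
    shared RNG, so results are reproducible under ``seed``) and the drop
    from baseline accuracy is averaged.  Categorical predictors are
    shuffled as whole columns, before one-hot encoding.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    frame = data.frame.reset_index(drop=True)
    labels = data.labels
    baseline = _accuracy(model, frame, labels)

    importances = {}
    for col in model.predictor_cols:
        accs = []
        for _ in range(n_repeats):
            shuffled = frame.copy()
            shuffled[col] = shuffled[col].to_numpy()[rng.permutation(len(shuffled))]
            accs.append(_accuracy(model, shuffled, labels))
        importances[col] = baseline - float(np.mean(accs))
    return pd.Series(importances, name="mean_decrease_accuracy")


def gini_importance(model: FittedForest) -> pd.Series:
    """Total impurity decrease per raw predictor.

    The forest records impurity decreases per encoded column; one-hot
    columns of a categorical predictor are summed back to the raw variable.
    """
    per_feature = pd.Series(
        model.estimator.feature_importances_, index=model.feature_columns
    )
    out = {}
    for col in model.predictor_cols:
        if col in model.categorical_levels:
            members = [f for f in model.feature_columns if f.startswith(f"{col}_")]
            out[col] = float(per_feature[members].sum())
        else:
            out[col] = float(per_feature[col])
    return pd.Series(out, name="mean_decrease_gini")


def importance_table(
    model: FittedForest,
    data: ModelingTable,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Both importance measures, one row per predictor."""
    acc = permutation_importance(model, data, n_repeats=n_repeats, seed=seed)
    gini = gini_importance(model)
    return pd.DataFrame({"mean_decrease_accuracy": acc, "mean_decrease_gini": gini})


def normalize_importance(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each importance measure by its own maximum (max becomes 1).

    Negative entries keep their sign.  A measure whose maximum is not
    positive cannot be meaningfully max-normalized and raises.
    """
    out = table.copy()
    for col in table.columns:
        top = table[col].max()
        if not top > 0:
            raise ValueError(f"cannot normalize '{col}': maximum is not positive")
        out[col] = table[col] / top
    return out


# ---------------------------------------------------------------------------
# plots


def plot_importance(table: pd.DataFrame, ax=None):
    """Horizontal bar chart of (normalized) importances, largest on top."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.3 * len(table) + 1))
    order = table.sort_values(table.columns[0])
    order.plot.barh(ax=ax)
    ax.set_xlabel("normalized importance")
    return ax


def plot_binned_panels(correlations: dict[str, BinnedCorrelation], ncols: int = 4):
    """Panel of scatter plots: per-bin predictor mean vs exceedance proportion.

    The Kendall tau-b annotation is bold when significant at the 95% level.
    """
    import matplotlib.pyplot as plt

    names = list(correlations)
    nrows = math.ceil(len(names) / ncols)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3 * ncols, 2.4 * nrows), squeeze=False
    )
    for k, name in enumerate(names):
        ax = axes[k // ncols][k % ncols]
        corr = correlations[name]
        ax.plot(corr.bin_means, corr.bin_proportions, "o-", ms=4)
        label = "undefined" if corr.tau_b is None else f"τ_b = {corr.tau_b:.2f}"
        ax.set_title(
            f"{name} ({label})",
            fontsize=9,
            fontweight="bold" if corr.significant else "normal",
        )
        ax.set_ylim(-0.05, 1.05)
    for k in range(len(names), nrows * ncols):
        axes[k // ncols][k % ncols].set_axis_off()
    fig.tight_layout()
    return fig
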