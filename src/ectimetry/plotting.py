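"""Optional cosmetic plots: group box plots and the ROC curve.

Requires matplotlib (the ``plot`` extra); imported lazily so the core
pipeline has no plotting dependency.
"""

from __future__ import annotations

import numpy as np


def box_plot(frame, value_col: str = "delta_linearity", group_col: str = "group",
             ax=None, ylabel: str = r"$(\Delta L)_{norm}$"):
    """Box plot (median, quartiles, 1.5 IQR whiskers, outliers) per group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    groups = sorted(frame[group_col].unique())
    data = [frame.loc[frame[group_col] == g, value_col].to_numpy() for g in groups]
    ax.boxplot(data, tick_labels=groups, whis=1.5)
    ax.set_ylabel(ylabel)
    return ax


def roc_plot(roc, ax=None, label: str | None = None):
    """Empirical ROC curve with the chosen operating point marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(3.5, 3.5))
    fpr = 1.0 - roc.specificity
    order = np.argsort(fpr)
    ax.plot(fpr[order], roc.sensitivity[order], "-",
            label=label or f"AUC = {roc.auc:.2f}")
    if roc.operating is not None:
        op = roc.operating
        ax.plot(1 - op.specificity_pct / 100, op.sensitivity_pct / 100, "o")
    ax.plot([0, 1], [0, 1], ":", color="gray")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    return ax
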