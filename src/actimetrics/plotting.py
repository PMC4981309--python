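"""Optional plotting helpers (requires matplotlib, the ``plot`` extra).

Thin wrappers that render the evaluation tables: per-activity metric
boxplots and ROC curve panels. All statistics are computed by
:mod:`actimetrics.evaluation`; nothing here alters the numbers.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .evaluation import ROCResult


def boxplot_by_activity(table, metric: str, ax=None, order: Sequence[str] | None = None):
    """Boxplot of pooled per-second metric values (or medians) by activity.

    ``table`` is a tidy DataFrame with columns ``activity`` and ``metric``.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    aliases = order or sorted(table["activity"].unique())
    data = [table.loc[table["activity"] == a, metric].to_numpy() for a in aliases]
    ax.boxplot(data, tick_labels=aliases, showfliers=False)
    ax.set_ylabel(metric)
    ax.set_xlabel("activity")
    return ax


def plot_roc_curves(results: Sequence[ROCResult], ax=None):
    """Overlay ROC curves with AUC in the legend, one line per task/metric."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for r in results:
        ax.plot(r.curve[:, 0], r.curve[:, 1], label=f"{r.label} (AUC {r.auc:.2f})")
    ax.plot([0, 1], [0, 1], ls=":", color="grey", lw=1)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize="small")
    return ax
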