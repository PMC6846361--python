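"""Optional panel plot of model performance (bias / IQR / RMSE / 1-P20).

One column per analysis group (pooled first, then each center), one row per
metric, point estimates with 95% bootstrap CI error bars per model.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

METRIC_LABELS = {
    "bias": "Residual median (mL/min)",
    "precision": "Residual IQR (mL/min)",
    "accuracy": "RMSE (mL/min)",
    "one_minus_p20": "1-P20",
}


def plot_metric_panel(reports: pd.DataFrame, path) -> None:
    """Save a metric panel figure.

    ``reports`` needs columns: group, model, and for each metric its value
    plus optional ``<metric>_lo``/``<metric>_hi`` CI columns.
    """
    groups = list(dict.fromkeys(reports["group"]))
    metrics = list(METRIC_LABELS)
    fig, axes = plt.subplots(
        len(metrics), len(groups),
        figsize=(2.2 * len(groups) + 1, 2.0 * len(metrics) + 1),
        sharey="row", squeeze=False,
    )
    for j, group in enumerate(groups):
        sub = reports[reports["group"] == group]
        for i, metric in enumerate(metrics):
            ax = axes[i][j]
            y = sub[metric].to_numpy()
            x = range(len(sub))
            if f"{metric}_lo" in sub:
                err = [
                    y - sub[f"{metric}_lo"].to_numpy(),
                    sub[f"{metric}_hi"].to_numpy() - y,
                ]
                ax.errorbar(x, y, yerr=err, fmt="o", ms=3, capsize=2, lw=1)
            else:
                ax.plot(x, y, "o", ms=3)
            ax.set_xticks(list(x))
            ax.set_xticklabels(sub["model"], rotation=90, fontsize=6)
            if i == 0:
                ax.set_title(group, fontsize=8)
            if j == 0:
                ax.set_ylabel(METRIC_LABELS[metric], fontsize=7)
            ax.tick_params(labelsize=6)
            if metric == "bias":
                ax.axhline(0.0, color="grey", lw=0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
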