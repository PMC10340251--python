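"""Bar-panel plots of per-class metric summaries (mean with sigma error bars)."""

from __future__ import annotations

import numpy as np

from .evaluation import METRIC_NAMES

__all__ = ["plot_metric_bars"]


def plot_metric_bars(summaries: dict, path=None, title: str | None = None):
    """Plot mean +/- sigma per metric for each class.

    ``summaries`` maps a class label to a ``{metric: (mean, std)}`` dict, as
    produced by ``SESet.train_summary``/``test_summary``.  Returns the figure;
    saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    classes = sorted(summaries)
    width = 0.8 / max(len(classes), 1)
    fig, axis = plt.subplots(figsize=(8, 4))
    x = np.arange(len(METRIC_NAMES))
    for i, cl in enumerate(classes):
        means = [summaries[cl][m][0] for m in METRIC_NAMES]
        stds = [summaries[cl][m][1] for m in METRIC_NAMES]
        axis.bar(x + i * width, means, width, yerr=stds, capsize=2, label=f"class {cl}")
    axis.set_xticks(x + width * (len(classes) - 1) / 2)
    axis.set_xticklabels(METRIC_NAMES)
    axis.set_ylim(0, 1.05)
    axis.set_ylabel("metric value")
    if title:
        axis.set_title(title)
    axis.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
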