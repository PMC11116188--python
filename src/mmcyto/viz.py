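"""Report figures: per-frequency regression panels and confusion heat maps."""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .fusion import VOL_COLUMN, pi_column, regress_vol_pi

__all__ = ["regression_panel", "confusion_heatmap"]


def regression_panel(table, frequencies, path=None):
    """Scatter of log10 PI vs log10 VOL with the fitted line, one panel per carrier."""
    n = len(frequencies)
    ncols = min(4, n)
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.8 * nrows),
                             squeeze=False)
    for ax, f in zip(axes.ravel(), frequencies):
        res = regress_vol_pi(table, f)
        x = np.log10(table[VOL_COLUMN].to_numpy(dtype=float))
        y = np.log10(table[pi_column(f)].to_numpy(dtype=float))
        ax.plot(x, y, ".", ms=3, alpha=0.5)
        xs = np.linspace(x.min(), x.max(), 2)
        ax.plot(xs, res.intercept + res.slope * xs, "r-", lw=1)
        ax.set_title(f"{f/1e3:g} kHz  $R^2$={res.r_squared:.2f}", fontsize=9)
        ax.set_xlabel("log10 VOL (µm³)", fontsize=8)
        ax.set_ylabel("log10 PI", fontsize=8)
    for ax in axes.ravel()[n:]:
        ax.axis("off")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def confusion_heatmap(confusion, class_order, path=None, title=""):
    """Heat map of a confusion matrix with per-cell counts."""
    c = np.asarray(confusion)
    fig, ax = plt.subplots(figsize=(3.4, 3.0))
    ax.imshow(c, cmap="Blues")
    for i in range(c.shape[0]):
        for j in range(c.shape[1]):
            ax.text(j, i, str(int(c[i, j])), ha="center", va="center", fontsize=8,
                    color="black" if c[i, j] < c.max() * 0.6 else "white")
    ax.set_xticks(range(len(class_order)), [str(k) for k in class_order])
    ax.set_yticks(range(len(class_order)), [str(k) for k in class_order])
    ax.set_xlabel("predicted class")
    ax.set_ylabel("true class")
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
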