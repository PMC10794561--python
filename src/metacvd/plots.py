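"""Optional plot outputs: KM contrast and ROC curves.

Matplotlib with the Agg backend; every function writes a file and returns
the path.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_km_contrast(km_top, km_bottom, path, title="Top vs bottom decile"):
    """Step plot of two survival curves (top/bottom score groups)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for (t, s), label, color in ((km_top, "top", "C3"),
                                 (km_bottom, "bottom", "C0")):
        ax.step(np.concatenate([[0], t]), np.concatenate([[1.0], s]),
                where="post", label=label, color=color)
    ax.set_xlabel("days since T2D onset")
    ax.set_ylabel("CVD-free survival")
    ax.set_ylim(0, 1.02)
    ax.legend()
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_roc(scores_by_model: dict, events, path):
    """Empirical ROC curves for several scores against one event vector."""
    events = np.asarray(events).astype(int)
    fig, ax = plt.subplots(figsize=(5, 4.5))
    for name, s in scores_by_model.items():
        s = np.asarray(s, dtype=float)
        order = np.argsort(-s, kind="stable")
        y = events[order]
        tpr = np.concatenate([[0], np.cumsum(y) / max(y.sum(), 1)])
        fpr = np.concatenate([[0], np.cumsum(1 - y) / max((1 - y).sum(), 1)])
        ax.plot(fpr, tpr, label=name)
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
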