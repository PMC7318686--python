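"""Minimal plotting: the class-annotated O² histogram and the
micelle/bicelle scatter panel."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_class_histogram(model, path, bins=20, title=""):
    """Histogram of O²_axis values with class centers and boundaries."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.hist(model.values, bins=bins, range=(0, 1), color="0.7", edgecolor="0.3")
    top = ax.get_ylim()[1]
    for b in model.boundaries:
        ax.axvline(b, color="k", ls="--", lw=0.8)
    for c, lab in zip(model.centers, model.labels):
        ax.text(c, top * 0.95, lab, ha="center", va="top")
    ax.set_xlabel(r"$O^2_{\mathrm{axis}}$")
    ax.set_ylabel("count")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_environment_scatter(pairs, path, labels=("micelle", "bicelle")):
    """Scatter of paired O² values between two environments."""
    x = np.array([a.O2_axis for a, _ in pairs])
    y = np.array([b.O2_axis for _, b in pairs])
    fig, ax = plt.subplots(figsize=(3.6, 3.6))
    ax.plot([0, 1], [0, 1], color="0.8", lw=1)
    ax.scatter(x, y, s=12, color="tab:purple")
    ax.set_xlabel(f"$O^2$ ({labels[0]})")
    ax.set_ylabel(f"$O^2$ ({labels[1]})")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
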