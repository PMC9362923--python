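"""Diagnostic plots: importance bar chart and selection curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_importance", "plot_selection_curves"]


def plot_importance(table: pd.DataFrame, path: str | Path, top: int = 50) -> None:
    """Bar chart of the top-ranked normalized importance scores."""
    sub = table.nsmallest(top, "rank")
    fig, ax = plt.subplots(figsize=(10, max(4, top * 0.18)))
    ax.barh(sub["feature"][::-1], sub["score"][::-1], color="seagreen")
    ax.set_xlabel("normalized Gini importance $S_f$")
    ax.set_title(f"Top {len(sub)} features")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_selection_curves(curves: pd.DataFrame, path: str | Path) -> None:
    """Prediction accuracy and OOB error versus tree count, per feature group."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4), sharex=True)
    for label, sub in curves.groupby("group"):
        ax1.plot(sub["n_trees"], sub["prediction_accuracy"], marker="o", label=f"group {label}")
        ax2.plot(sub["n_trees"], sub["oob_error"], marker="o", label=f"group {label}")
    ax1.set_xlabel("number of trees")
    ax1.set_ylabel("prediction accuracy")
    ax2.set_xlabel("number of trees")
    ax2.set_ylabel("out-of-bag error")
    ax1.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
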