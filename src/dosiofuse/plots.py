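"""Plotting helpers: C-index heatmaps and Kaplan-Meier curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["plot_cindex_heatmap", "plot_km_curves"]


def plot_cindex_heatmap(tidy: pd.DataFrame, path: str | Path,
                        strategy: str | None = None) -> Path:
    """Selector x model heatmap of mean C-index (optionally one strategy)."""
    df = tidy if strategy is None else tidy[tidy["strategy"] == strategy]
    pivot = df.pivot_table(index="selector", columns="model",
                           values="cindex_mean", aggfunc="mean")
    fig, ax = plt.subplots(figsize=(1.2 * len(pivot.columns) + 2,
                                    0.6 * len(pivot) + 2))
    im = ax.imshow(pivot.to_numpy(), cmap="viridis", vmin=0.5, vmax=1.0)
    ax.set_xticks(range(len(pivot.columns)), pivot.columns, rotation=45)
    ax.set_yticks(range(len(pivot.index)), pivot.index)
    for i in range(len(pivot.index)):
        for j in range(len(pivot.columns)):
            ax.text(j, i, f"{pivot.iloc[i, j]:.2f}", ha="center", va="center",
                    color="white", fontsize=8)
    fig.colorbar(im, ax=ax, label="C-index")
    ax.set_title(strategy or "all strategies")
    path = Path(path)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_km_curves(curves: dict, path: str | Path, logrank_p: float | None = None) -> Path:
    """Kaplan-Meier curves for the risk groups of :func:`km_stratify`."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, km in curves.items():
        km.plot_survival_function(ax=ax)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    if logrank_p is not None:
        ax.set_title(f"log-rank p = {logrank_p:.2e}")
    path = Path(path)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
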