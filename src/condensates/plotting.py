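"""Summary plots for the simulation experiments."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .lattice import ASK3, OBSTACLE, LatticeState

__all__ = ["plot_state", "plot_sweep_summary", "plot_expansion_summary"]


def plot_state(state: LatticeState, ax=None, title: str | None = None):
    """Render a lattice snapshot: ASK3 units red, obstacles black."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    occ = state.occupancy()
    rgb = np.ones((*occ.shape, 3))
    rgb[occ == ASK3] = (0.85, 0.1, 0.1)
    rgb[occ == OBSTACLE] = (0.1, 0.1, 0.1)
    ax.imshow(rgb, origin="lower", interpolation="nearest")
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    ax.set_title(title or f"step {state.step}")
    return ax


def plot_sweep_summary(summary, out: str | Path | None = None):
    """Cluster count and mean size vs grid width, mean +- SEM."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    w = summary["width"]
    axes[0].errorbar(w, summary["mean_count"], yerr=summary["sem_count"], fmt="o-")
    axes[0].set_ylabel("clusters (count)")
    axes[1].errorbar(w, summary["mean_size"], yerr=summary["sem_size"], fmt="o-")
    axes[1].axhline(6, ls="--", c="grey", lw=1)
    axes[1].set_ylabel("mean cluster size (units)")
    for ax in axes:
        ax.set_xlabel("grid width (squares)")
    fig.tight_layout()
    if out:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig


def plot_expansion_summary(summary, out: str | Path | None = None):
    """Cluster count and mean size vs time after grid expansion."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    t = summary["time_t"]
    axes[0].errorbar(t, summary["mean_count"], yerr=summary["sem_count"], fmt="-")
    axes[0].axhline(summary["mean_count"].iloc[0], ls="--", c="red", lw=1)
    axes[0].set_ylabel("clusters (count)")
    axes[1].errorbar(t, summary["mean_size"], yerr=summary["sem_size"], fmt="-")
    axes[1].axhline(summary["mean_size"].iloc[0], ls="--", c="red", lw=1)
    axes[1].axhline(6, ls="--", c="grey", lw=1)
    axes[1].set_ylabel("mean cluster size (units)")
    for ax in axes:
        ax.set_xlabel("time t after expansion (1e5 steps)")
    fig.tight_layout()
    if out:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig
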