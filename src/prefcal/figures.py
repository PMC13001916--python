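"""Diagnostic figures, each a pure function of stored metrics tables."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def _band(ax, summary: pd.DataFrame, metric: str, color: str, label: str):
    sub = summary[summary["metric"] == metric]
    ax.plot(sub["epoch"], sub["median"], color=color, label=label)
    if (sub["q75"] - sub["q25"]).abs().max() > 0:
        ax.fill_between(sub["epoch"], sub["q25"], sub["q75"], color=color, alpha=0.2)


def learning_curves(summary: pd.DataFrame, out: Path,
                    baseline: pd.DataFrame | None = None) -> None:
    """Held-out MSE and MAE over epochs, median with IQR band across seeds."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for ax, metric in zip(axes, ("mse", "mae")):
        _band(ax, summary, metric, "C0", "policy run")
        if baseline is not None:
            _band(ax, baseline, metric, "C1", "fixed alpha=0.5 baseline")
        ax.set_xlabel("epoch")
        ax.set_ylabel(metric.upper())
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)


def alpha_trajectory(summary: pd.DataFrame, out: Path,
                     optimal_alpha: float | None = None) -> None:
    """Median learned alpha with IQR band; optional offline-optimal reference."""
    fig, ax = plt.subplots(figsize=(5.5, 3.5))
    _band(ax, summary, "alpha_hat", "C0", "alpha (policy mean)")
    ax.axhline(0.5, color="grey", ls=":", lw=1, label="equal weight")
    if optimal_alpha is not None:
        ax.axhline(optimal_alpha, color="C3", ls="--", lw=1,
                   label=f"offline optimal alpha = {optimal_alpha:g}")
    ax.set_xlabel("epoch")
    ax.set_ylabel("alpha")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)


def stakeholder_mae_curves(summary: pd.DataFrame, out: Path) -> None:
    fig, ax = plt.subplots(figsize=(5.5, 3.5))
    _band(ax, summary, "mae_comm", "C0", "vs community labels (held out)")
    _band(ax, summary, "mae_phys", "C2", "vs physician-style labels (queried)")
    ax.set_xlabel("epoch")
    ax.set_ylabel("stakeholder MAE")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)


def reward_curve(summary: pd.DataFrame, out: Path) -> None:
    fig, ax = plt.subplots(figsize=(5.5, 3.5))
    _band(ax, summary, "reward", "C0", "epoch-mean reward")
    ax.set_xlabel("epoch")
    ax.set_ylabel("reward (agreement)")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)


def sweep_panel(sweeps: list[dict], out: Path) -> None:
    """Plateau MSE vs fixed alpha, one curve per feedback condition."""
    fig, ax = plt.subplots(figsize=(5.5, 3.5))
    for i, sw in enumerate(sweeps):
        label = (f"sigma={sw['condition']['sigma_comm']:g}, "
                 f"beta={sw['condition']['beta_phys']:g}")
        ax.plot(sw["alpha_grid"], sw["mse_per_alpha"], marker="o", ms=3,
                color=f"C{i}", label=label)
        ax.axvline(sw["optimal_alpha"], color=f"C{i}", ls=":", lw=1)
    ax.set_xlabel("fixed alpha")
    ax.set_ylabel("plateau MSE vs true outcome")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)


def heatmap_panel(sigma_grid: np.ndarray, beta_grid: np.ndarray,
                  alpha_matrix: np.ndarray, out: Path) -> None:
    """Terminal learned alpha over (physician bias, community noise)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(alpha_matrix, origin="lower", vmin=0, vmax=1, cmap="coolwarm",
                   aspect="auto")
    ax.set_xticks(range(len(beta_grid)), [f"{b:g}" for b in beta_grid])
    ax.set_yticks(range(len(sigma_grid)), [f"{s:g}" for s in sigma_grid])
    ax.set_xlabel("physician bias beta")
    ax.set_ylabel("community noise sigma")
    for i in range(len(sigma_grid)):
        for j in range(len(beta_grid)):
            ax.text(j, i, f"{alpha_matrix[i, j]:.2f}", ha="center", va="center",
                    fontsize=7)
    fig.colorbar(im, ax=ax, label="terminal alpha")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
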