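"""Matplotlib rendering of evaluation artifacts (PNG)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import AttentionSummary, EvalReport

__all__ = ["plot_confusion", "plot_attention_heatmaps", "plot_gate_trajectory"]

_CLASS_NAMES = ["S0/ext", "S0/flex", "S1/ext", "S1/flex", "S2/ext", "S2/flex"]


def plot_confusion(report: EvalReport, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(report.confusion, cmap="Blues")
    ax.set_xticks(range(6), _CLASS_NAMES, rotation=45, ha="right")
    ax.set_yticks(range(6), _CLASS_NAMES)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(6):
        for j in range(6):
            ax.text(j, i, str(report.confusion[i, j]), ha="center", va="center",
                    fontsize=8)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_attention_heatmaps(summary: AttentionSummary, path_emg, path_kine) -> None:
    from .synthetic import MUSCLES

    for data, labels, path in (
        (summary.emg_per_action, MUSCLES, path_emg),
        (summary.kine_per_action, ("velocity", "acceleration", "jerk"), path_kine),
    ):
        fig, ax = plt.subplots(figsize=(6, 6))
        im = ax.imshow(data, aspect="auto", cmap="viridis")
        ax.set_xticks(range(len(labels)), labels, rotation=45, ha="right")
        ax.set_yticks(range(18), [f"A{a}" for a in range(1, 19)])
        ax.set_ylabel("action")
        fig.colorbar(im, ax=ax, label="mean attention weight")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def plot_gate_trajectory(history: list[dict], path) -> None:
    epochs = [h["epoch"] for h in history if "w_emg" in h]
    if not epochs:
        return
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(epochs, [h["w_emg"] for h in history if "w_emg" in h], label="w_emg")
    ax.plot(epochs, [h["w_kine"] for h in history if "w_kine" in h], label="w_kine")
    ax.set_xlabel("epoch")
    ax.set_ylabel("mean gate weight")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
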