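"""Optional diagnostic plots (cross-section overlays, Z-vs-time profiles)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_cross_section", "plot_z_profile"]


def plot_cross_section(outcomes_df, radius: float, path) -> None:
    """Risk and final points on the fistula cross-section with the lumen circle."""
    fig, ax = plt.subplots(figsize=(5, 5))
    theta = np.linspace(0, 2 * np.pi, 256)
    ax.plot(radius * np.cos(theta), radius * np.sin(theta), "k-", lw=1, label="lumen wall")
    ax.scatter(outcomes_df["x1_mm"], outcomes_df["y1_mm"], s=18, marker="v", label="risk P1")
    ax.scatter(outcomes_df["x3_mm"], outcomes_df["y3_mm"], s=18, marker="^", label="risk P3")
    ax.scatter(outcomes_df["xf_mm"], outcomes_df["yf_mm"], s=18, marker="o", label="final")
    ax.set_xlabel("lateral x (mm)")
    ax.set_ylabel("vertical y (mm)")
    ax.set_aspect("equal")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_z_profile(trial, path) -> None:
    """Vertical tip position over time with phase bands for one segmented trial."""
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.plot(trial.times, trial.tips[:, 2], lw=1)
    colors = {1: "#cce5ff", 2: "#ffe5cc", 3: "#ccffcc"}
    for phase in (1, 2, 3):
        i, j = trial.phase_slice(phase)
        ax.axvspan(trial.times[i], trial.times[j], color=colors[phase], alpha=0.5)
    for t in trial.em_times:
        ax.axvline(t, color="k", lw=0.5, ls="--")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("tip Z (mm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
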