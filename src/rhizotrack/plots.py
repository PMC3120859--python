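"""Figure-style summaries: velocity fields, divisions, trajectories."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .kinematics import VelocityField, profile_1d

__all__ = [
    "plot_velocity_field",
    "plot_division_summary",
    "plot_frequency_split",
]


def plot_velocity_field(field: VelocityField, path=None):
    """Heatmap plus median/quartile profile for each velocity component."""
    fig, axes = plt.subplots(3, 2, figsize=(9, 10))
    labels = {
        "v_m": "$v_m$ (µm/min)",
        "v_rho": r"$v_\rho$ (µm/min)",
        "rho_v_theta": r"$\rho\,v_\theta$ (µm/min)",
    }
    for row, comp in enumerate(labels):
        data = np.where(field.mask, field.median[comp], np.nan)
        im = axes[row, 0].imshow(
            data.T,
            origin="lower",
            aspect="auto",
            extent=[
                field.m_edges[0],
                field.m_edges[-1],
                field.rho_edges[0],
                field.rho_edges[-1],
            ],
        )
        axes[row, 0].set_xlabel("m (µm)")
        axes[row, 0].set_ylabel(r"$\rho$ (µm)")
        fig.colorbar(im, ax=axes[row, 0], label=labels[comp])
        m, med, q25, q75 = profile_1d(field, comp)
        axes[row, 1].plot(m, med, "k-", label="median")
        axes[row, 1].plot(m, q25, "k--", lw=0.8)
        axes[row, 1].plot(m, q75, "k--", lw=0.8)
        axes[row, 1].set_xlabel("m (µm)")
        axes[row, 1].set_ylabel(labels[comp])
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_division_summary(stats: dict, path=None):
    """Temporal histogram, (m, rho) scatter and polar orientation
    histograms of detected divisions."""
    fig = plt.figure(figsize=(10, 8))
    ax1 = fig.add_subplot(2, 2, 1)
    hist, edges = stats["time_histogram"]
    if len(edges) > 1:
        ax1.bar(edges[:-1] / 60.0, hist, width=np.diff(edges) / 60.0, align="edge")
    ax1.set_xlabel("time (h)")
    ax1.set_ylabel("divisions")
    ax2 = fig.add_subplot(2, 2, 2)
    pos = stats["positions_m_rho"]
    if len(pos):
        ax2.scatter(pos[:, 0], pos[:, 1], s=14, c="crimson", marker="+")
    ax2.set_xlabel("m (µm)")
    ax2.set_ylabel(r"$\rho$ (µm)")
    for k, key in enumerate(("angles_m_rho", "angles_m_rhotheta")):
        ax = fig.add_subplot(2, 2, 3 + k, projection="polar")
        angles = stats[key]
        if len(angles):
            ax.hist(angles, bins=24)
        ax.set_title(
            r"$\Delta m$–$\Delta\rho$" if k == 0 else r"$\Delta m$–$\rho\Delta\theta$"
        )
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_frequency_split(times, values, low, high, path=None):
    """One trajectory coordinate with its low/high frequency parts."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 3), sharey=True)
    hours = np.asarray(times) / 60.0
    axes[0].plot(hours, high)
    axes[0].set_title("high frequency")
    axes[1].plot(hours, low)
    axes[1].set_title("low frequency")
    for ax in axes:
        ax.set_xlabel("time (h)")
    axes[0].set_ylabel("position (µm)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
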