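"""Figure rendering for the adherence pipeline.

Every figure has a CSV counterpart written by the pipeline, so the
plots themselves are presentation only.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .sop import SOPMatrix

__all__ = [
    "plot_sop",
    "plot_calibration",
    "plot_width_over_time",
    "plot_partial_effect",
]


def plot_sop(sops: SOPMatrix, path, stacked: bool = True, title=None):
    """Per-patient state occupancy probabilities over 90-day windows."""
    fig, ax = plt.subplots(figsize=(7, 4))
    K = sops.n_states
    labels = [f"state {j}" for j in range(1, K + 1)]
    if stacked:
        ax.stackplot(sops.windows, sops.probs.T, labels=labels,
                     colors=plt.cm.RdYlGn(np.linspace(0.05, 0.95, K)))
    else:
        for j in range(K):
            ax.plot(sops.windows, sops.probs[:, j], label=labels[j])
    ax.set_xlabel("90-day window")
    ax.set_ylabel("state occupancy probability")
    ax.set_ylim(0, 1)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=6, ncol=2, loc="center left", bbox_to_anchor=(1, 0.5))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_calibration(table: pd.DataFrame, path, smooth=None):
    """Decile calibration points with the identity reference line."""
    fig, ax = plt.subplots(figsize=(5, 5))
    if "stratum" in table.columns:
        for name, g in table.groupby("stratum"):
            ax.plot(g["mean_predicted"], g["mean_observed"], "o-", label=name)
        ax.legend()
    else:
        ax.plot(table["mean_predicted"], table["mean_observed"], "o",
                color="tab:blue")
    if smooth is not None:
        ax.plot(smooth[0], smooth[1], "-", color="tab:orange", label="GAM")
    lims = [1, 10]
    ax.plot(lims, lims, "--", color="grey")
    ax.set_xlabel("mean predicted state")
    ax.set_ylabel("mean observed state")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_width_over_time(width_df: pd.DataFrame, path):
    """SOP distribution width (IQR length) per state over time."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for state, g in width_df.groupby("state"):
        ax.plot(g["window_index"], g["width"], label=f"state {state}")
    ax.set_xlabel("90-day window")
    ax.set_ylabel("SOP distribution width (IQR length)")
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_partial_effect(curve: pd.DataFrame, variable: str, path):
    """Partial log-odds effect with a delta-method 95% band."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve["grid"], curve["effect"], color="tab:blue")
    ax.fill_between(curve["grid"], curve["lower"], curve["upper"],
                    alpha=0.25, color="tab:blue")
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel(variable)
    ax.set_ylabel("log-odds effect")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
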