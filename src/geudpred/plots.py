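"""Secondary figure artifacts; the CSV tables are the canonical outputs."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .synth import STRUCTURE_BRAIN, STRUCTURE_LEFT, STRUCTURE_RIGHT

__all__ = ["plot_sweep", "plot_mean_dose_window", "plot_average_dvh"]


def plot_sweep(sweeps: dict, path: str | Path) -> Path:
    """Optimal a and mAUC of EUD_V_D against the threshold dose D."""
    fig, (ax_a, ax_m) = plt.subplots(1, 2, figsize=(9, 3.5))
    for name, sweep in sweeps.items():
        ax_a.plot(sweep.threshold_doses, sweep.a_opt, marker="o", label=name)
        ax_m.plot(sweep.threshold_doses, sweep.m_auc, marker="o", label=name)
    ax_a.set_xlabel("threshold D (Gy)")
    ax_a.set_ylabel("optimal a")
    ax_m.set_xlabel("threshold D (Gy)")
    ax_m.set_ylabel("mAUC")
    ax_a.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_mean_dose_window(window: pd.DataFrame, path: str | Path) -> Path:
    """AUC of the mean dose of V_D per threshold, with reference lines."""
    classes = window["structure_class"].unique()
    fig, axes = plt.subplots(1, len(classes), figsize=(4.5 * len(classes), 3.5))
    axes = np.atleast_1d(axes)
    for ax, structure_class in zip(axes, classes):
        sub = window[window["structure_class"] == structure_class]
        ax.plot(
            sub["threshold_gy"], sub["auc_mean_dose"], marker="o",
            label="mean dose of V_D",
        )
        ax.axhline(
            sub["ref_auc_whole_eud"].iloc[0], color="gray", ls="--",
            label="whole-volume EUD (mAUC)",
        )
        ax.axhline(
            sub["ref_auc_best_point"].iloc[0], color="black", ls=":",
            label="best dose/volume point",
        )
        ax.set_title(structure_class)
        ax.set_xlabel("threshold D (Gy)")
        ax.set_ylabel("AUC")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_average_dvh(cohort, path: str | Path) -> Path:
    """Cohort-average relative cumulative DVH per structure, overlaid."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for structure in (STRUCTURE_BRAIN, STRUCTURE_LEFT, STRUCTURE_RIGHT):
        curves = [
            o.dvh.relative_volume() for o in cohort if o.structure == structure
        ]
        if not curves:
            continue
        edges = next(
            o.dvh.dose_edges for o in cohort if o.structure == structure
        )
        ax.plot(edges, 100 * np.mean(curves, axis=0), label=structure)
    ax.set_xlabel("dose (Gy)")
    ax.set_ylabel("average relative volume (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
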