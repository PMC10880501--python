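"""Simple diagnostic plots: QC violins, scale-free fit, KM and ROC curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_qc(metrics: pd.DataFrame, path) -> None:
    fig, axes = plt.subplots(1, 3, figsize=(9, 3))
    for ax, col in zip(axes, ["nCount", "nFeature", "percent_mt"]):
        ax.violinplot(metrics[col].to_numpy(), showmedians=True)
        ax.set_title(col)
        ax.set_xticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_scale_free_profile(profile: pd.DataFrame, target_r2: float, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(profile["power"], profile["signed_r2"], "o-")
    ax.axhline(target_r2, color="red", ls="--", lw=0.8)
    ax.set_xlabel("soft-threshold power")
    ax.set_ylabel("signed scale-free fit $R^2$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_km(result, path) -> None:
    """Step plot of the two Kaplan–Meier curves of a survival comparison."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for name, curve in result.curves.items():
        ax.step(curve.index, curve["S"], where="post", label=name)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_title(f"{result.endpoint}: log-rank p = {result.p:.3g}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roc(curve: pd.DataFrame, auc: float, path) -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(curve["fpr"], curve["tpr"])
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(f"AUC = {auc:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
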