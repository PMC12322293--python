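"""Figure helpers: MF group distributions, metric panels, and the
MF_R-vs-MF_NR risk map."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .containers import PhenotypeTable
from .module_factor import ModuleFactorMatrix


def plot_mf_distributions(mf: ModuleFactorMatrix, pheno: PhenotypeTable, path) -> None:
    """Per-feature strip/box plots of normalized MFs split by R/NR."""
    feats = mf.values.copy()
    if mf.merged is not None:
        feats = pd.concat([feats, mf.merged], axis=1)
    labels = pheno.labels.loc[feats.index]
    n = feats.shape[1]
    fig, axes = plt.subplots(1, n, figsize=(2.2 * n, 3.2), squeeze=False)
    rng = np.random.default_rng(0)
    for ax, feat in zip(axes[0], feats.columns):
        for i, grp in enumerate(["R", "NR"]):
            vals = feats.loc[labels == grp, feat].to_numpy()
            ax.boxplot([vals], positions=[i], widths=0.5, showfliers=False)
            ax.scatter(np.full(vals.size, i) + rng.uniform(-0.12, 0.12, vals.size), vals, s=8, alpha=0.6)
        ax.set_xticks([0, 1], ["R", "NR"])
        ax.set_title(feat, fontsize=9)
    fig.suptitle("Normalized module factors by outcome")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_metric_panel(per_repeat: pd.DataFrame, path) -> None:
    """Box panel of precision/recall/accuracy/AUC over repeats."""
    metrics = ["precision", "recall", "accuracy", "auc"]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    data = [per_repeat[m].dropna().to_numpy(dtype=float) for m in metrics]
    ax.boxplot(data, tick_labels=metrics)
    ax.set_ylim(-0.05, 1.05)
    ax.set_ylabel("score")
    ax.set_title("Repeated-split test metrics")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_risk_map(mf: ModuleFactorMatrix, pheno: PhenotypeTable, path) -> None:
    """MF_R vs MF_NR scatter colored by outcome (R expected lower right)."""
    if mf.merged is None or not {"MF_R", "MF_NR"} <= set(mf.merged.columns):
        raise ValueError("risk map needs both merged features MF_R and MF_NR")
    labels = pheno.labels.loc[mf.merged.index]
    fig, ax = plt.subplots(figsize=(4.2, 4))
    for grp, color in [("R", "tab:red"), ("NR", "tab:blue")]:
        sub = mf.merged.loc[labels == grp]
        ax.scatter(sub["MF_R"], sub["MF_NR"], s=18, alpha=0.75, c=color, label=grp)
    ax.set_xlabel("MF_R")
    ax.set_ylabel("MF_NR")
    ax.legend(title="outcome")
    ax.set_title("Rejection-risk map")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
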