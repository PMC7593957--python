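"""QC and model plots (RSD vs intensity, PCA scores, distance-to-model)."""

from __future__ import annotations

from pathlib import Path

import numpy as np


def _plt():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def plot_rsd_vs_intensity(mean_intensity, rsd_percent, path: str | Path,
                          benchmark: float = 15.0) -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean_intensity, rsd_percent, s=4, alpha=0.5)
    ax.axhline(benchmark, color="red", lw=1, ls="--", label=f"{benchmark:g}% benchmark")
    ax.set_xscale("log")
    ax.set_xlabel("mean intensity (a.u.)")
    ax.set_ylabel("RSD (%)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_scores(scores, labels, path: str | Path) -> None:
    plt = _plt()
    scores = np.asarray(scores)
    fig, ax = plt.subplots(figsize=(5, 4))
    for lab in sorted(set(labels)):
        idx = [i for i, l in enumerate(labels) if l == lab]
        ax.scatter(scores[idx, 0], scores[idx, 1], s=18, label=str(lab))
    ax.set_xlabel("PC1 score")
    ax.set_ylabel("PC2 score")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_dmodx(sample_ids, residual_sd, critical_value, path: str | Path) -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(len(sample_ids))
    ax.bar(x, residual_sd)
    ax.axhline(critical_value, color="red", lw=1, ls="--", label="critical value")
    ax.set_xticks(x)
    ax.set_xticklabels(sample_ids, rotation=90, fontsize=6)
    ax.set_ylabel("normalized residual SD (DModX)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
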