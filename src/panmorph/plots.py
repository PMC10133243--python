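"""Figure helpers: overlap heatmap and Kaplan-Meier curves."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .morphospace import OverlapMatrix
from .survival import KmCurve


def plot_overlap_heatmap(matrix: OverlapMatrix, path: str | Path | None = None):
    """Row-wise heatmap of the asymmetric morphospace-overlap matrix."""
    vals = matrix.values
    fig, ax = plt.subplots(figsize=(1.2 * len(vals) + 2, 1.0 * len(vals) + 1.5))
    im = ax.imshow(vals.to_numpy(dtype=float), vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(vals.columns)), vals.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(vals.index)), vals.index)
    for i in range(len(vals.index)):
        for j in range(len(vals.columns)):
            v = vals.iat[i, j]
            if np.isfinite(v):
                ax.text(j, i, f"{v:.2f}", ha="center", va="center",
                        color="white" if v < 0.5 else "black", fontsize=8)
    ax.set_xlabel("inside group")
    ax.set_ylabel("group")
    fig.colorbar(im, ax=ax, label="morphospace overlap")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def plot_km(curves: Mapping[str, KmCurve], path: str | Path | None = None):
    """Step-plot Kaplan-Meier curves per group."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, c in curves.items():
        ax.step(c.times, c.survival, where="post",
                label=f"{name} (n={c.n}, events={c.n_events})")
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
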