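"""Bland-Altman report figures (points, bias line, limits of agreement)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .agreement import bland_altman


def bland_altman_panel(ax, reference, method, title: str = "") -> None:
    """One Bland-Altman panel: mean vs difference, bias and 1.96 SD limits."""
    ref = np.asarray(reference, dtype=float)
    met = np.asarray(method, dtype=float)
    ba = bland_altman(ref, met)
    mean = (ref + met) / 2.0
    diff = met - ref
    ax.scatter(mean, diff, s=18, color="tab:blue", zorder=3)
    ax.axhline(ba.bias, color="k", lw=1.2)
    for y in (ba.loa_low, ba.loa_high):
        ax.axhline(y, color="k", lw=0.8, ls="--")
    ax.set_title(f"{title}\nbias {ba.bias:+.1f}", fontsize=8)
    ax.set_xlabel("mean of methods (%)", fontsize=7)
    ax.set_ylabel("method − histology (%)", fontsize=7)
    ax.tick_params(labelsize=7)


def bland_altman_grid(metrics: pd.DataFrame, modality_pairs: dict, path) -> None:
    """Group x modality grid of Bland-Altman panels, one figure."""
    groups = list(dict.fromkeys(metrics["group"]))
    mods = list(modality_pairs)
    fig, axes = plt.subplots(len(groups), len(mods),
                             figsize=(2.4 * len(mods), 2.2 * len(groups)),
                             squeeze=False)
    for i, g in enumerate(groups):
        sub = metrics[metrics["group"] == g]
        for j, mod in enumerate(mods):
            mcol, rcol = modality_pairs[mod]
            ax = axes[i][j]
            pairs = sub[[rcol, mcol]].dropna()
            if len(pairs) < 2:
                ax.set_axis_off()
                continue
            bland_altman_panel(ax, pairs[rcol], pairs[mcol], f"{g}: {mod}")
    fig.tight_layout()
    fig.savefig(path, dpi=110, metadata={"Software": None})
    plt.close(fig)
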