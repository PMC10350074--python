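"""Figures: per-pair group curves and the all-pairs -log10(p) heatmap."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .errors import DesignError
from .pipeline import PairwiseResults

__all__ = ["plot_group_curves", "plot_pvalue_heatmap"]

_GROUP_COLORS = ("#c62828", "#1565c0", "#2e7d32", "#6a1b9a", "#ef6c00")


def plot_group_curves(results: PairwiseResults, pair: tuple, path: str | Path):
    """Per-subject mean g curves (thin) and group mean curves (thick) for one
    pair, with the null reference line at 0 for adjusted curves and at 1 for
    raw ones."""
    cs = results.curve_sets.get(pair)
    if cs is None:
        raise KeyError(f"pair {pair!r} was not analysed")
    reason = cs.untestable_reason()
    if reason is not None:
        raise DesignError(f"pair {pair!r} is untestable: {reason}")
    fig, ax = plt.subplots(figsize=(6, 4))
    r = cs.grid.interior
    for k, group in enumerate(cs.groups):
        color = _GROUP_COLORS[k % len(_GROUP_COLORS)]
        stack = []
        for subject in cs.subjects(group):
            v = cs.subject_mean(group, subject)
            stack.append(v)
            ax.plot(r, v, color=color, alpha=0.3, lw=0.8)
        ax.plot(r, np.mean(stack, axis=0), color=color, lw=2.5, label=str(group))
    ref = 0.0 if results.kind == "g-adjusted" else 1.0
    ax.axhline(ref, color="k", ls=":", lw=1)
    ax.set_xlabel("radius r")
    ylabel = "adjusted g(r)" if results.kind == "g-adjusted" else "g(r)"
    ax.set_ylabel(ylabel)
    ax.set_title(f"pair ({pair[0]}, {pair[1]})")
    ax.legend(title="group", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_pvalue_heatmap(results: PairwiseResults, method: str = "univ", path: str | Path = "heatmap.png"):
    """M x M heatmap of -log10(p); untestable pairs are hatched grey."""
    mat = results.neglog10_matrix(method)
    M = len(results.cell_types)
    fig, ax = plt.subplots(figsize=(1.0 * M + 2.5, 1.0 * M + 2))
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("#bbbbbb")
    masked = np.ma.masked_invalid(mat.to_numpy())
    im = ax.imshow(masked, cmap=cmap, origin="upper")
    for i in range(M):
        for j in range(M):
            if masked.mask is not np.ma.nomask and np.ndim(masked.mask) and masked.mask[i, j]:
                ax.text(j, i, "n/a", ha="center", va="center", fontsize=8, color="k")
    ax.set_xticks(range(M), results.cell_types, rotation=45, ha="right")
    ax.set_yticks(range(M), results.cell_types)
    ax.set_xlabel("cell type m'")
    ax.set_ylabel("cell type m")
    ax.set_title(f"-log10(p), {method}")
    fig.colorbar(im, ax=ax, shrink=0.8, label="-log10(p)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
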