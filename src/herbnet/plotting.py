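"""Matplotlib emitters for the standard pipeline figures.

Content mirrors the conventional network-pharmacology plots: an
enrichment dot/bar plot driven by Count, adjusted p and GeneRatio, a
docking-affinity heat map, and trajectory traces. Styling is deliberately
minimal; these are working figures, not publication renderings.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .enrichment import EnrichmentResult
from .md import TrajectorySeries


def enrichment_dotplot(
    results: Sequence[EnrichmentResult], path: Union[str, Path]
) -> None:
    """Dot plot: GeneRatio on x, terms on y, dot size = Count, color = p.adjust."""
    if not results:
        raise ValueError("no enrichment results to plot")
    results = sorted(results, key=lambda r: r.p_adjust)
    ratios = [float(r.gene_ratio) for r in results]
    names = [f"{r.term_name} ({r.category})" for r in results]
    counts = [r.count for r in results]
    padj = [r.p_adjust for r in results]
    fig, ax = plt.subplots(figsize=(7, 0.35 * len(results) + 1.5))
    sc = ax.scatter(ratios, range(len(results)), s=[20 * c for c in counts],
                    c=padj, cmap="RdYlGn")
    ax.set_yticks(range(len(results)), names)
    ax.invert_yaxis()
    ax.set_xlabel("GeneRatio")
    fig.colorbar(sc, ax=ax, label="p.adjust")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def affinity_heatmap(matrix: pd.DataFrame, path: Union[str, Path]) -> None:
    """Ligand x receptor best-affinity heat map (kcal/mol)."""
    fig, ax = plt.subplots(figsize=(1 + 0.6 * matrix.shape[1],
                                    1 + 0.5 * matrix.shape[0]))
    im = ax.imshow(matrix.to_numpy(dtype=float), cmap="coolwarm_r", aspect="auto")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=45, ha="right")
    ax.set_yticks(range(matrix.shape[0]), matrix.index)
    fig.colorbar(im, ax=ax, label="affinity (kcal/mol)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def trajectory_plot(
    series: Sequence[TrajectorySeries], path: Union[str, Path], ylabel: str = "RMSD (nm)"
) -> None:
    """Overlaid trajectory traces (RMSD or SASA) against time."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for s in series:
        ax.plot(s.times, s.values, lw=0.8, label=s.label or None)
    ax.set_xlabel("time (ns)")
    ax.set_ylabel(ylabel)
    if any(s.label for s in series):
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
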