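"""Figure panels mirroring the standard displays of this analysis:
the bimodal coverage-ratio histogram, per-sex expression boxplots with the
log2(M/F) density, and the shared-X observed/expected matrix."""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .sexlink import AUTOSOME, X, LinkageCall, LinkageModel

__all__ = ["coverage_histogram", "expression_panels", "shared_x_matrix"]


def coverage_histogram(calls: Sequence[LinkageCall], model: LinkageModel, path) -> None:
    """log2(M/F coverage) histogram, X calls in red, autosomes in grey."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ratios = {X: [], AUTOSOME: []}
    for c in calls:
        if c.linkage in ratios:
            ratios[c.linkage].append(c.log2_mf_coverage)
    finite = [r for v in ratios.values() for r in v]
    lo, hi = min(finite), max(finite)
    bins = np.arange(lo, hi + model.bin_width, model.bin_width)
    ax.hist(ratios[AUTOSOME], bins=bins, color="0.6", label="autosomes")
    ax.hist(ratios[X], bins=bins, color="firebrick", label="X")
    ax.axvline(model.a_median, color="k", lw=1)
    ax.axvline(model.threshold, color="k", lw=1, ls="--")
    ax.set_xlabel("log2(male/female genomic coverage)")
    ax.set_ylabel("scaffolds")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def expression_panels(
    values: Mapping[str, Mapping[str, Sequence[float]]], path, title: str = ""
) -> None:
    """Female/male FPKM boxplots and log2(M/F) densities for X vs autosomes.

    ``values[cls][panel]`` for cls in {X, autosome} and panel in
    {female, male, log2_mf} as produced by the per-species pipeline.
    """
    fig, axes = plt.subplots(1, 3, figsize=(9, 3))
    for ax, panel, label in zip(
        axes[:2], ("female", "male"), ("female FPKM", "male FPKM")
    ):
        data = [np.log2(np.asarray(values[X][panel], dtype=float)),
                np.log2(np.asarray(values[AUTOSOME][panel], dtype=float))]
        ax.boxplot(data, tick_labels=["X", "A"], showfliers=False)
        ax.set_ylabel(f"log2 {label}")
    ax = axes[2]
    for cls, color in ((AUTOSOME, "0.5"), (X, "firebrick")):
        vals = np.asarray(values[cls]["log2_mf"], dtype=float)
        hist, edges = np.histogram(vals, bins=40, density=True)
        ax.plot(edges[:-1] + np.diff(edges) / 2, hist, color=color,
                label="X" if cls == X else "autosomes")
    a_median = float(np.median(values[AUTOSOME]["log2_mf"]))
    ax.axvline(a_median, color="k", lw=1)
    ax.axvline(a_median - 1.0, color="k", lw=1, ls="--")
    ax.set_xlabel("log2(M/F expression)")
    ax.legend(frameon=False)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def shared_x_matrix(pair_ratios: Mapping[tuple[str, str], float], path) -> None:
    """Observed/expected shared X-linked orthologs as an annotated matrix."""
    names = sorted({n for pair in pair_ratios for n in pair})
    size = len(names)
    grid = np.full((size, size), np.nan)
    for (a, b), ratio in pair_ratios.items():
        i, j = names.index(a), names.index(b)
        grid[i, j] = grid[j, i] = ratio
    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(grid, cmap="YlOrRd", vmin=0)
    ax.set_xticks(range(size), names, rotation=45, ha="right")
    ax.set_yticks(range(size), names)
    for i in range(size):
        for j in range(size):
            if i != j and not np.isnan(grid[i, j]):
                ax.text(j, i, f"{grid[i, j]:.1f}", ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label="observed/expected shared X genes")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
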