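"""Figure rendering for pipeline reports.

Every figure drawn here has a TSV twin written by the pipeline containing
exactly the plotted numbers; the figures are presentation only.  Row/column
order is the input order — clustering of heatmap axes is cosmetic and off by
default.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .variants import CLASS_COLORS
from .phenotypes import LABELS, PHENOTYPE_COLORS


def _finish(fig, path: str) -> None:
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def frequency_heatmap(values: pd.DataFrame, path: str, title: str) -> None:
    """Item x population frequency heatmap (variant-MAF or HAF style)."""
    fig, ax = plt.subplots(
        figsize=(max(4, 0.35 * values.shape[1] + 2),
                 max(3, 0.25 * values.shape[0] + 1.5)))
    im = ax.imshow(values.to_numpy(dtype=float), aspect="auto",
                   cmap="YlOrRd", vmin=0, vmax=1)
    ax.set_xticks(range(values.shape[1]), values.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(values.shape[0]), values.index, fontsize=6)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="frequency")
    _finish(fig, path)


def delta_maf_chart(ft_values: pd.DataFrame, delta: pd.Series, path: str,
                    top_k: int = 10) -> None:
    """Per-group frequencies of the most differentiated variants."""
    top = delta.dropna().sort_values(ascending=False).head(top_k)
    fig, ax = plt.subplots(figsize=(max(5, 0.8 * len(top)), 4))
    x = np.arange(len(top))
    for j, col in enumerate(ft_values.columns):
        ax.scatter(x, ft_values.loc[top.index, col], label=col, s=25)
    ax.set_xticks(x, top.index, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("variant-allele frequency")
    ax.set_title(f"top {len(top)} variants by frequency spread across groups")
    ax.legend(fontsize=7)
    _finish(fig, path)


def class_by_chromosome(counts: pd.DataFrame, path: str) -> None:
    """Stacked functional-class counts per chromosome."""
    fig, ax = plt.subplots(figsize=(max(5, 0.5 * len(counts)), 4))
    bottom = np.zeros(len(counts))
    for cls in counts.columns:
        vals = counts[cls].to_numpy(dtype=float)
        ax.bar(counts.index.astype(str), vals, bottom=bottom,
               color=CLASS_COLORS.get(cls, "steelblue"), label=cls)
        bottom += vals
    ax.set_xlabel("chromosome")
    ax.set_ylabel("variants")
    ax.set_title("functional class by chromosome")
    ax.legend(fontsize=8)
    _finish(fig, path)


def unmatched_rate_chart(rates: pd.DataFrame, path: str) -> None:
    """Grouped bars: per-gene unmatched strand proportion per population."""
    fig, ax = plt.subplots(figsize=(max(5, 0.9 * len(rates)), 4))
    x = np.arange(len(rates))
    n = len(rates.columns)
    width = 0.8 / max(n, 1)
    for j, col in enumerate(rates.columns):
        ax.bar(x + j * width, rates[col].to_numpy(dtype=float), width,
               label=col)
    ax.set_xticks(x + 0.4, rates.index, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("unmatched strand proportion")
    ax.set_title("strands matching no known haplotype, per gene")
    ax.legend(fontsize=7)
    _finish(fig, path)


def phenotype_bars(freqs: pd.DataFrame, gene: str, path: str) -> None:
    """Stacked WT/WT, WT/V, V/V bars per population for one gene."""
    sub = freqs.loc[gene]
    fig, ax = plt.subplots(figsize=(max(4, 0.6 * len(sub)), 4))
    bottom = np.zeros(len(sub))
    for lab in LABELS:
        vals = sub[lab].fillna(0).to_numpy(dtype=float)
        ax.bar(sub.index, vals, bottom=bottom,
               color=PHENOTYPE_COLORS[lab], label=lab)
        bottom += vals
    ax.set_ylabel("frequency among assigned samples")
    ax.set_title(f"{gene}: phenotype distribution")
    ax.legend(fontsize=8)
    _finish(fig, path)


def gene_track(defs, classes: pd.Series, maf_values: pd.DataFrame,
               gene: str, path: str) -> None:
    """Genomic track for one gene: position axis with variants coloured by
    functional class, over a per-population frequency heatmap."""
    gd = [d for d in defs if d.gene == gene]
    if not gd:
        return
    gd = sorted(gd, key=lambda d: d.pos)
    rsids = [d.rsid for d in gd]
    fig, (ax0, ax1) = plt.subplots(
        2, 1, figsize=(max(5, 0.6 * len(gd)), 5),
        height_ratios=[1, 3], sharex=False)
    for i, d in enumerate(gd):
        ax0.scatter(d.pos, 0, color=CLASS_COLORS.get(classes.get(d.rsid), "grey"),
                    s=60, zorder=3)
    ax0.set_yticks([])
    ax0.set_xlabel(f"chromosome {gd[0].chrom} position")
    ax0.set_title(f"{gene}: variant functional classes and frequencies")
    sub = maf_values.loc[[r for r in rsids if r in maf_values.index]]
    im = ax1.imshow(sub.to_numpy(dtype=float).T, aspect="auto",
                    cmap="YlOrRd", vmin=0, vmax=1)
    ax1.set_xticks(range(len(sub.index)), sub.index, rotation=90, fontsize=7)
    ax1.set_yticks(range(len(sub.columns)), sub.columns, fontsize=7)
    fig.colorbar(im, ax=ax1, label="frequency")
    _finish(fig, path)
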