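"""Publication-ready plots: count heatmap, connectivity scatter, rank scatter.

Every plot writes a machine-readable sidecar TSV (``<plot>.data.tsv``)
holding exactly the plotted coordinates and classes, so downstream tools
(and tests) read the data instead of parsing images, and the figures can
be regenerated in any plotting package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from .combine import band_size
from .model import (
    QUADRANT_CLASSES,
    CombinedTable,
    InputError,
    LiteratureMatrix,
    NetworkMetrics,
)

#: Above this many genes, per-gene tick labels are unreadable and dropped.
HEATMAP_LABEL_CUTOFF = 100

QUADRANT_PALETTE = {
    "high_conn_high_prec": "#d62728",
    "high_conn_low_prec": "#1f77b4",
    "other": "#b0b0b0",
}


@dataclass(frozen=True)
class PlotConfig:
    output_format: str = "png"
    dpi: int = 200
    log_scale_heatmap: bool = True
    label_top_n: int = 10

    def __post_init__(self) -> None:
        if self.output_format not in ("png", "svg", "pdf"):
            raise InputError(f"unknown output format {self.output_format!r}")
        if self.dpi <= 0:
            raise InputError("dpi must be positive")
        if self.label_top_n < 0:
            raise InputError("label_top_n must be >= 0")


def sidecar_path(image_path: Path) -> Path:
    image_path = Path(image_path)
    return image_path.with_name(image_path.stem + ".data.tsv")


def _write_sidecar(df: pd.DataFrame, image_path: Path) -> Path:
    path = sidecar_path(image_path)
    # repr float formatting keeps the sidecar byte-identical across runs
    df.to_csv(path, sep="\t", index=True, lineterminator="\n")
    return path


def _save(fig, path: Path, config: PlotConfig) -> None:
    path = Path(path)
    if not path.parent.exists():
        raise InputError(f"output directory does not exist: {path.parent}")
    fig.savefig(path, dpi=config.dpi, bbox_inches="tight")
    plt.close(fig)


def plot_heatmap(
    matrix: LiteratureMatrix,
    ordering: pd.Series,
    path: Path,
    config: PlotConfig = PlotConfig(),
) -> Path:
    """Heatmap of publication counts, genes ordered by precedence rank.

    Genes run down the rows (rank 1 first), terms across the columns in
    user order.  Cell colour encodes log10(count+1) by default since
    publication counts span orders of magnitude; set
    ``config.log_scale_heatmap=False`` for a linear scale.
    """
    df = pd.DataFrame(
        matrix.counts, index=list(matrix.genes), columns=list(matrix.terms)
    )
    order = ordering.sort_values().index
    df = df.loc[order]
    df.index.name = "gene"
    values = np.log10(df + 1) if config.log_scale_heatmap else df

    show_labels = len(df) <= HEATMAP_LABEL_CUTOFF
    fig, ax = plt.subplots(
        figsize=(2 + 0.8 * len(matrix.terms), max(3, min(0.25 * len(df), 20)))
    )
    sns.heatmap(
        values,
        ax=ax,
        cmap="viridis",
        yticklabels=show_labels,
        cbar_kws={
            "label": "log10(publications + 1)"
            if config.log_scale_heatmap
            else "publications"
        },
    )
    ax.set_xlabel("search term")
    ax.set_ylabel("gene (by precedence rank)")
    _save(fig, path, config)

    sidecar = df.copy()
    sidecar.insert(0, "precedence_rank", ordering.loc[sidecar.index].astype(int))
    sidecar["gene_labels_shown"] = show_labels
    _write_sidecar(sidecar, path)
    return Path(path)


def plot_network_scatter(
    metrics: NetworkMetrics, path: Path, config: PlotConfig = PlotConfig()
) -> Path:
    """Scatter of interactions (x) versus percent connectivity (y).

    The top-right corner holds the most connected genes; the top
    ``label_top_n`` genes by network rank are annotated.
    """
    from .network import rank_network

    ranks, _ = rank_network(metrics)
    df = metrics.table.copy()
    df["connectivity_rank"] = ranks

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(df["degree"], df["connectivity_pct"], s=25, alpha=0.7,
               color="#1f77b4", edgecolor="none")
    for gene, row in df[df["connectivity_rank"] <= config.label_top_n].iterrows():
        ax.annotate(gene, (row["degree"], row["connectivity_pct"]),
                    fontsize=7, xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("number of interactions (degree)")
    ax.set_ylabel("connectivity (%)")
    ax.set_ylim(-5, 105)
    _save(fig, path, config)
    _write_sidecar(df, path)
    return Path(path)


def plot_rank_scatter(
    combined: CombinedTable, path: Path, config: PlotConfig = PlotConfig()
) -> Path:
    """Scatter of precedence rank (x) versus connectivity rank (y).

    Rank 1 sits at the origin, so high-precedence high-connectivity genes
    appear close to it.  Guide lines mark the threshold bands at k and
    N-k+1, and points are coloured by quadrant class.
    """
    df = combined.table.copy()
    n = len(df)
    k = band_size(n, combined.threshold)

    fig, ax = plt.subplots(figsize=(6, 5))
    for cls in QUADRANT_CLASSES:
        sub = df[df["quadrant_class"] == cls]
        if len(sub) == 0:
            continue
        ax.scatter(sub["precedence_rank"], sub["connectivity_rank"],
                   s=25, alpha=0.8, color=QUADRANT_PALETTE[cls],
                   edgecolor="none", label=cls)
    for x in (k + 0.5, n - k + 0.5):
        ax.axvline(x, color="grey", linestyle="--", linewidth=0.8)
    ax.axhline(k + 0.5, color="grey", linestyle="--", linewidth=0.8)
    top = df[df["quadrant_class"] != "other"]
    for gene, row in top.head(config.label_top_n).iterrows():
        ax.annotate(gene, (row["precedence_rank"], row["connectivity_rank"]),
                    fontsize=7, xytext=(3, 3), textcoords="offset points")
    ax.set_xlim(0, n + 1)
    ax.set_ylim(0, n + 1)
    ax.set_xlabel("precedence rank")
    ax.set_ylabel("connectivity rank")
    ax.legend(loc="lower right", fontsize=7)
    _save(fig, path, config)
    _write_sidecar(df, path)
    return Path(path)
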