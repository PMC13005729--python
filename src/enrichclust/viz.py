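"""Plot-ready structures and rendered figures.

The heatmap matrix holds -log10(pooled p) per cluster x condition cell
(0 where a cluster was not observed in a condition: absence of evidence is
drawn blank, not imputed). Optional hierarchical grouping uses average
linkage on Euclidean distances with labels pre-sorted so leaf orders are
deterministic. Every rendered figure is accompanied by a side-car CSV table
holding the exact numbers drawn, so users can restyle plots themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .clustering import ThresholdProfile
from .exceptions import ConfigurationError, InputError
from .summary import ClusterSummaryRow

FORMATS = ("png", "svg", "pdf")


def _cell_label(condition: str, regulation: str) -> str:
    return condition if regulation == "all" else f"{condition} ({regulation})"


@dataclass(frozen=True)
class HeatmapBundle:
    """-log10(pooled p) matrix with display orders and term-count bars."""

    matrix: pd.DataFrame          # rows: cluster labels, cols: condition cells
    row_order: tuple[str, ...]
    col_order: tuple[str, ...]
    row_bar: pd.Series            # n_terms_total per cluster row

    @property
    def ordered(self) -> pd.DataFrame:
        return self.matrix.loc[list(self.row_order), list(self.col_order)]


@dataclass(frozen=True)
class BubbleTable:
    """One bubble per summary row: size = -log10 p, color = gene count."""

    table: pd.DataFrame  # condition, regulation, annotation, size, color


def _dendro_order(frame: pd.DataFrame) -> list[str]:
    if len(frame) < 3:
        return list(frame.index)
    z = linkage(frame.to_numpy(), method="average", metric="euclidean")
    return [frame.index[i] for i in leaves_list(z)]


def heatmap_bundle(
    rows: Sequence[ClusterSummaryRow],
    cluster_rows: bool = True,
    cluster_cols: bool = True,
) -> HeatmapBundle:
    """Build the heatmap matrix and hierarchical display orders."""
    if not rows:
        raise InputError("no summary rows to plot")
    data: dict[tuple[str, str], float] = {}
    bars: dict[str, int] = {}
    for r in rows:
        row_label = r.annotation or f"Cluster {r.cluster_id}"
        col_label = _cell_label(r.condition, r.regulation)
        data[(row_label, col_label)] = -np.log10(r.pooled_p)
        bars[row_label] = r.n_terms_total
    row_labels = sorted({k[0] for k in data})
    col_labels = sorted({k[1] for k in data})
    matrix = pd.DataFrame(0.0, index=row_labels, columns=col_labels)
    for (rl, cl), v in data.items():
        matrix.loc[rl, cl] = v
    row_order = _dendro_order(matrix) if cluster_rows else row_labels
    col_order = _dendro_order(matrix.T) if cluster_cols else col_labels
    return HeatmapBundle(
        matrix=matrix,
        row_order=tuple(row_order),
        col_order=tuple(col_order),
        row_bar=pd.Series(bars, name="n_terms_total").loc[row_labels],
    )


def bubble_table(rows: Sequence[ClusterSummaryRow]) -> BubbleTable:
    """Flatten summary rows into the bubble-plot table."""
    if not rows:
        raise InputError("no summary rows to plot")
    records = [
        {
            "condition": r.condition,
            "regulation": r.regulation,
            "annotation": r.annotation or f"Cluster {r.cluster_id}",
            "size": -np.log10(r.pooled_p),
            "color": r.n_genes,
        }
        for r in rows
    ]
    table = pd.DataFrame.from_records(records).sort_values(
        ["annotation", "condition", "regulation"], kind="mergesort"
    )
    return BubbleTable(table=table.reset_index(drop=True))


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".csv")


def _save(fig: plt.Figure, path: Path, fmt: str) -> None:
    # strip volatile metadata so identical runs give identical bytes
    metadata = {"Date": None} if fmt in ("svg", "pdf") else {}
    if fmt == "pdf":
        metadata = {"CreationDate": None}
    fig.savefig(path, format=fmt, metadata=metadata, dpi=150)
    plt.close(fig)


def render(obj, path: str | Path, format: str | None = None) -> None:
    """Render a HeatmapBundle, BubbleTable or ThresholdProfile to a file.

    The figure format comes from ``format`` or the path suffix (png, svg or
    pdf) and the numbers behind the figure are written next to it as
    ``<figure>.csv``.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in FORMATS:
        raise ConfigurationError(f"unknown figure format {fmt!r}; use one of {FORMATS}")
    if isinstance(obj, HeatmapBundle):
        _render_heatmap(obj, path, fmt)
    elif isinstance(obj, BubbleTable):
        _render_bubble(obj, path, fmt)
    elif isinstance(obj, ThresholdProfile):
        _render_thresholds(obj, path, fmt)
    else:
        raise ConfigurationError(f"cannot render object of type {type(obj).__name__}")


def _render_heatmap(bundle: HeatmapBundle, path: Path, fmt: str) -> None:
    mat = bundle.ordered
    n_rows, n_cols = mat.shape
    fig, (ax, ax_bar) = plt.subplots(
        1,
        2,
        figsize=(2.2 + 0.7 * n_cols, 1.5 + 0.45 * n_rows),
        gridspec_kw={"width_ratios": [max(n_cols, 1), max(n_cols, 1) * 0.25]},
        constrained_layout=True,
    )
    im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(n_cols), mat.columns, rotation=45, ha="right")
    ax.set_yticks(range(n_rows), mat.index)
    fig.colorbar(im, ax=ax, label="-log10(pooled p)", shrink=0.8)
    bars = bundle.row_bar.loc[list(bundle.row_order)]
    ax_bar.barh(range(n_rows), bars.to_numpy(), color="grey")
    ax_bar.set_ylim(n_rows - 0.5, -0.5)
    ax_bar.set_yticks([])
    ax_bar.set_xlabel("terms")
    _save(fig, path, fmt)
    mat.to_csv(_sidecar_path(path))


def _render_bubble(bubble: BubbleTable, path: Path, fmt: str) -> None:
    t = bubble.table
    cells = sorted(
        {(c, r) for c, r in zip(t["condition"], t["regulation"])}
    )
    annots = sorted(t["annotation"].unique())
    x_of = {cell: i for i, cell in enumerate(cells)}
    y_of = {a: i for i, a in enumerate(annots)}
    xs = [x_of[(c, r)] for c, r in zip(t["condition"], t["regulation"])]
    ys = [y_of[a] for a in t["annotation"]]
    fig, ax = plt.subplots(
        figsize=(2.5 + 0.8 * len(cells), 1.5 + 0.4 * len(annots)),
        constrained_layout=True,
    )
    sizes = 30.0 + 40.0 * t["size"].to_numpy()
    sc = ax.scatter(xs, ys, s=sizes, c=t["color"], cmap="plasma")
    ax.set_xticks(
        range(len(cells)), [_cell_label(c, r) for c, r in cells],
        rotation=45, ha="right",
    )
    ax.set_yticks(range(len(annots)), annots)
    ax.invert_yaxis()
    fig.colorbar(sc, ax=ax, label="genes in cluster")
    handles, labels = sc.legend_elements(prop="sizes", num=3)
    ax.legend(
        handles, labels, title="-log10(pooled p)",
        loc="upper left", bbox_to_anchor=(1.25, 1.0),
    )
    _save(fig, path, fmt)
    t.to_csv(_sidecar_path(path), index=False)


def _render_thresholds(profile: ThresholdProfile, path: Path, fmt: str) -> None:
    t = profile.table
    fig, axes = plt.subplots(3, 1, sharex=True, figsize=(6, 7), constrained_layout=True)
    for ax, col, label in zip(
        axes,
        ["n_clusters", "n_components", "modularity"],
        ["clusters", "connected components", "modularity"],
    ):
        ax.plot(t["ts"], t[col], marker="o")
        ax.set_ylabel(label)
    axes[-1].set_xlabel("pruning threshold ts")
    _save(fig, path, fmt)
    t.to_csv(_sidecar_path(path), index=False)
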