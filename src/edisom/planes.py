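"""Component plane presentations and the gene-panel fold-change report.

A component plane recolors the trained map by one stage's codebook values:
plane *k* is simply column *k* of the codebook laid out on the lattice.
All planes share symmetric color limits anchored at 0 log2FC (red positive,
blue negative) so that stages are directly comparable.  Planes are exported
as plain TSV matrices; PNG rendering is optional so tests stay image-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import ClusterPartition
from .preprocess import FoldChangeMatrix
from .som import SOMGrid

__all__ = [
    "ComponentPlane",
    "component_planes",
    "plane_frame",
    "render_planes",
    "gene_panel_report",
    "UNCLUSTERED_MARKER",
]

#: Marker used in the gene-panel report for genes that failed the regulation filter.
UNCLUSTERED_MARKER = "-"


@dataclass(frozen=True)
class ComponentPlane:
    stage_label: str
    unit_values: np.ndarray
    color_limits: tuple[float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "unit_values", np.asarray(self.unit_values, dtype=float))
        lo, hi = self.color_limits
        if not np.isclose(lo, -hi):
            raise ValueError(f"color limits must be symmetric about zero, got {self.color_limits}")


def component_planes(grid: SOMGrid) -> list[ComponentPlane]:
    """One plane per stage; plane k carries codebook column k verbatim."""
    if not grid.trained:
        raise ValueError("grid must be trained before building component planes")
    m = float(np.max(np.abs(grid.codebook)))
    if m == 0.0:  # degenerate all-zero map: widen so the scale is drawable
        m = 1.0
    labels = grid.stage_labels or tuple(f"stage_{i+1}" for i in range(grid.n_stages))
    return [
        ComponentPlane(stage_label=lab, unit_values=grid.codebook[:, j], color_limits=(-m, m))
        for j, lab in enumerate(labels)
    ]


def plane_frame(plane: ComponentPlane, grid: SOMGrid) -> pd.DataFrame:
    """TSV-ready layout of one plane: unit index, axial (q, r), value."""
    return pd.DataFrame(
        {
            "unit": np.arange(grid.n_units),
            "q": grid.unit_coords[:, 0],
            "r": grid.unit_coords[:, 1],
            "value": plane.unit_values,
        }
    )


def render_planes(grid: SOMGrid, out_path: str | Path, dpi: int = 150) -> Path:
    """Render all component planes as hexagon maps into one PNG.

    Diverging colormap anchored at 0 (blue = repressed, red = induced);
    shared limits across stages.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import RegularPolygon

    planes = component_planes(grid)
    vmin, vmax = planes[0].color_limits
    cmap = plt.get_cmap("RdBu_r")
    ncols = min(len(planes), 3)
    nrows = -(-len(planes) // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 3.0 * nrows), squeeze=False)
    for ax in axes.ravel():
        ax.set_axis_off()
    radius = 0.5 / np.cos(np.pi / 6.0)  # circumradius of a unit-spaced hexagon
    for plane, ax in zip(planes, axes.ravel()):
        for (x, y), v in zip(grid.cartesian, plane.unit_values):
            color = cmap((v - vmin) / (vmax - vmin))
            ax.add_patch(
                RegularPolygon((x, y), numVertices=6, radius=radius, orientation=0.0,
                               facecolor=color, edgecolor="white", linewidth=0.3)
            )
        ax.set_xlim(grid.cartesian[:, 0].min() - 1, grid.cartesian[:, 0].max() + 1)
        ax.set_ylim(grid.cartesian[:, 1].min() - 1, grid.cartesian[:, 1].max() + 1)
        ax.set_aspect("equal")
        ax.set_title(plane.stage_label, fontsize=9)
    sm = plt.cm.ScalarMappable(cmap=cmap, norm=plt.Normalize(vmin, vmax))
    fig.colorbar(sm, ax=axes, shrink=0.7, label="log2 fold change")
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=dpi)
    plt.close(fig)
    return out_path


def gene_panel_report(
    fc_full: FoldChangeMatrix,
    p: ClusterPartition,
    panel: list[str],
) -> pd.DataFrame:
    """Per-gene stage fold changes with cluster membership for a chosen panel.

    ``fc_full`` is the pre-filter fold-change matrix, so the report can show
    genes that did not qualify for clustering; those carry the hyphen
    marker in the cluster column.  Rows follow panel order.
    """
    index = {tid: i for i, tid in enumerate(fc_full.transcript_ids)}
    rows = []
    for gene in panel:
        if gene not in index:
            raise KeyError(f"panel gene {gene!r} not present in the fold-change matrix")
        row: dict[str, object] = {"gene": gene}
        for lab, v in zip(fc_full.stage_labels, fc_full.values[index[gene]]):
            row[f"log2fc_{lab}"] = v
        cluster = p.gene_cluster.get(gene)
        row["cluster"] = str(cluster) if cluster is not None else UNCLUSTERED_MARKER
        rows.append(row)
    columns = ["gene"] + [f"log2fc_{lab}" for lab in fc_full.stage_labels] + ["cluster"]
    return pd.DataFrame(rows, columns=columns)
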